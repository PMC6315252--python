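# Portuguese function words suppressed in word-frequency tables.
a
à
ao
aos
as
às
até
com
como
da
das
de
dela
dele
deles
depois
do
dos
e
é
ela
elas
ele
eles
em
entre
era
eram
essa
essas
esse
esses
esta
está
estamos
estão
este
estes
eu
foi
foram
há
isso
isto
já
lhe
mais
mas
me
mesmo
meu
minha
muito
na
não
nas
nem
no
nos
nós
nossa
nosso
num
numa
o
os
ou
para
pela
pelas
pelo
pelos
por
qual
quando
que
quem
se
sem
ser
seu
seus
só
sobre
sua
suas
também
te
tem
têm
tinha
um
uma
você
vocês
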