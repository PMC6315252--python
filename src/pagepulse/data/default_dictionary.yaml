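# Demonstration keyword dictionary for the 8 default content-analysis
# categories of Brazilian cancer-related Facebook pages. Small and
# illustrative: real deployments should grow their own lists (all
# inflections enumerated; a word may appear in only one category).
# Deliberately excluded, being too generic to discriminate: câncer,
# quimioterapia, tratamento-agnostic disease terms.
testimonies_or_real_life_stories:
  - história
  - histórias
  - depoimento
  - depoimentos
  - relato
  - relatos
  - superação
  - vivência
  - experiência
  - sobrevivente
  - sobreviventes
solidarity:
  - doador
  - doadores
  - doadora
  - doadoras
  - doação
  - doações
  - doar
  - doe
  - solidariedade
  - campanha
  - sangue
  - cabelo
  - cabelos
anniversaries:
  - aniversário
  - aniversários
  - dia
  - comemoração
  - comemorações
  - celebração
  - celebrar
  - parabéns
  - anos
  - data
science_and_health:
  - pesquisa
  - pesquisas
  - pesquisadores
  - cientistas
  - ciência
  - estudo
  - estudos
  - descoberta
  - descobertas
  - células
  - imunoterapia
  - diagnóstico
  - melanoma
  - transplante
events:
  - evento
  - eventos
  - palestra
  - palestras
  - corrida
  - caminhada
  - inscrição
  - inscrições
  - encontro
  - congresso
  - seminário
institutional:
  - instituto
  - instituição
  - hospital
  - fundação
  - equipe
  - projeto
  - projetos
  - unidade
  - sede
  - missão
  - parceria
  - voluntários
risk_factors:
  - fumo
  - fumar
  - cigarro
  - cigarros
  - tabagismo
  - álcool
  - obesidade
  - sedentarismo
  - prevenção
  - prevenir
  - risco
  - riscos
beauty:
  - maquiagem
  - lenço
  - lenços
  - peruca
  - perucas
  - beleza
  - autoestima
  - turbante
  - turbantes
  - visual
  - estilo
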