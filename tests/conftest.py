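from datetime import datetime, timezone
from zoneinfo import ZoneInfo

import pytest

from pagepulse import Corpus, Post, default_dictionary

TZ = ZoneInfo("America/Sao_Paulo")


def make_post(
    post_id="p1",
    text="",
    reactions=0,
    shares=0,
    comments=0,
    group="informative",
    timestamp=None,
    post_type="photo",
    **kwargs,
):
    return Post(
        post_id=post_id,
        page_id=kwargs.pop("page_id", "page1"),
        group=group,
        timestamp=timestamp or datetime(2017, 3, 20, 14, 30, tzinfo=TZ),
        post_type=post_type,
        text=text,
        reactions=reactions,
        shares=shares,
        comments=comments,
        **kwargs,
    )


@pytest.fixture(scope="session")
def demo_dictionary():
    return default_dictionary()


@pytest.fixture
def small_corpus():
    return Corpus(
        posts=[
            make_post("a", "Vamos falar sobre a pesquisa de células", reactions=10, shares=2, comments=1),
            make_post("b", "Doe sangue, seja um doador", reactions=5, shares=8, comments=4),
            make_post("c", "zyba zyco zydu", reactions=1, shares=0, comments=0),
        ],
        provenance="handmade",
    )
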