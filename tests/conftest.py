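import pytest

from tcmkg.corpus_io import AnnotatedArticle, Article, EntitySpan
from tcmkg.schema import load_default_schema


@pytest.fixture(scope="session")
def schema():
    return load_default_schema()


def make_article(tokens, aid="A000001", sep="，"):
    """Build an annotated article from (type_or_None, text) pairs.

    ``None`` types contribute literal text; entity tokens become spans.
    Tokens are joined by ``sep`` unless a token is literal punctuation.
    """
    parts = []
    spans = []
    pos = 0
    for i, (etype, text) in enumerate(tokens):
        if i and not (etype is None and text in "。，、；"):
            prev_literal = tokens[i - 1][0] is None and tokens[i - 1][1] in "。，、；"
            if not prev_literal:
                parts.append(sep)
                pos += len(sep)
        if etype is not None:
            spans.append(EntitySpan(start=pos, end=pos + len(text),
                                    entity_type=etype, surface=text))
        parts.append(text)
        pos += len(text)
    art = Article(article_id=aid, source_book_title="test book", text="".join(parts))
    return AnnotatedArticle(article=art, spans=tuple(spans))


@pytest.fixture
def mk_article():
    return make_article
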