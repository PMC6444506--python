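import pytest

from cohortqa import (GeneratorConfig, Pipeline, fixture_graph, fixture_lexicon,
                      generate_graph)

#: the running demonstration question (unsegmented CJK original; its
#: English gloss is "How many female patients with hyperglycemia and no
#: hypertension have low levels of glucose tests after they took
#: hypoglycemic drugs?")
CANONICAL_ZH = "患有高血糖没有患有高血压的病人吃了降血糖类药后葡萄糖化验结果偏低的女患者数量?"

SEQ_14 = ("Relation Instance Not Relation Instance Class Relation Instance "
          "TimeOperator Instance Property EnumValue Class StatisticOperator").split()
SEQ_16 = ("Relation Instance Not Relation Instance Class Relation Instance "
          "TimeOperator Instance Property EnumValue Property EnumValue Class "
          "StatisticOperator").split()

CANONICAL_EXPR = (
    "(<patient, suffer, hyperglycemia> (not <patient, suffer, hypertension>)) "
    "after <patient, take, hypoglycemic drugs> "
    "after (<patient, have test, blood glucose> <blood glucose, test result, low>) "
    "<patient, sex, female> <patient, count, ?>")


@pytest.fixture(scope="session")
def fg():
    return fixture_graph()


@pytest.fixture(scope="session")
def zh_lexicon(fg):
    return fixture_lexicon(fg, "zh")


@pytest.fixture(scope="session")
def en_lexicon(fg):
    return fixture_lexicon(fg, "en")


@pytest.fixture(scope="session")
def zh_pipeline(fg, zh_lexicon):
    return Pipeline(fg, zh_lexicon)


@pytest.fixture(scope="session")
def gen_graph():
    return generate_graph(GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def gen_pipeline(gen_graph):
    return Pipeline(gen_graph, fixture_lexicon(gen_graph, "en"))
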