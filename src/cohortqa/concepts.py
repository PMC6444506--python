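"""The 14 concept types that serve as grammar terminals."""

from __future__ import annotations

from enum import Enum


class ConceptType(str, Enum):
    RELATION = "Relation"
    INSTANCE = "Instance"
    CLASS = "Class"
    PROPERTY = "Property"
    NUMBER = "Number"
    ENUM_VALUE = "EnumValue"
    TIME_VALUE = "TimeValue"
    RANGE_SEPARATOR = "RangeSeparator"
    TIME_OPERATOR = "TimeOperator"
    LOGICAL_OPERATOR = "LogicalOperator"
    STATISTIC_OPERATOR = "StatisticOperator"
    ARITHMETIC_OPERATOR = "ArithmeticOperator"
    UNIT = "Unit"
    NOT = "Not"

    def __str__(self) -> str:  # terminal name as it appears in the grammar
        return self.value


#: concept types resolved by closed word lists in the lexicon
CLOSED_TYPES = frozenset({
    ConceptType.NOT, ConceptType.LOGICAL_OPERATOR, ConceptType.TIME_OPERATOR,
    ConceptType.STATISTIC_OPERATOR, ConceptType.ARITHMETIC_OPERATOR,
    ConceptType.UNIT, ConceptType.RANGE_SEPARATOR,
})

#: content types resolved by similarity-based linking
CONTENT_TYPES = frozenset({
    ConceptType.RELATION, ConceptType.INSTANCE, ConceptType.CLASS,
    ConceptType.PROPERTY, ConceptType.ENUM_VALUE,
})

STATISTICS = ("list", "count", "sum", "avg", "distribution", "ratio")
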