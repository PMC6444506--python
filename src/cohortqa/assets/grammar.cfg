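# Context-free grammar over the 14 concept-type terminals.
# Terminals are quoted; one nonterminal per line, alternatives separated by |.
S -> QueryItem | QueryItem S | Condition S | Condition 'Class' S
Condition -> RelationCondition | PropertyCondition
Condition -> Condition 'LogicalOperator' Condition
Condition -> RelationCondition 'TimeOperator' Condition
RelationCondition -> 'Relation' 'Instance' | 'Not' 'Relation' 'Instance' | TimeBlock 'Relation' 'Instance' | TimeBlock 'Not' 'Relation' 'Instance'
TimeBlock -> 'TimeValue' | 'TimeValue' 'LogicalOperator' | 'TimeValue' 'RangeSeparator' 'TimeValue'
PropertyCondition -> 'Property' PropertyValue | 'Instance' 'Property' PropertyValue
PropertyValue -> 'EnumValue' | NumericValue | NumericRange | TimeBlock
NumericValue -> 'Number' | 'Number' 'Unit'
NumericRange -> NumericValue 'RangeSeparator' NumericValue | 'ArithmeticOperator' NumericValue
QueryItem -> 'Property' 'StatisticOperator' | 'StatisticOperator' 'Property' | 'Relation' 'StatisticOperator' 'Class' | 'Instance' 'Property' 'StatisticOperator' | 'StatisticOperator'
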