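# surface	canonical_id	concept_type	synonyms	cls
没有	not	Not	不|无
和	and	LogicalOperator	并且
或	or	LogicalOperator	或者
后	after	TimeOperator	之后|然后
先	before	TimeOperator	之前
数量	count	StatisticOperator	多少|几个
平均	avg	StatisticOperator	平均值
总和	sum	StatisticOperator	合计
比例	ratio	StatisticOperator	占比
分布	distribution	StatisticOperator
哪些	list	StatisticOperator	列出
超过	gt	ArithmeticOperator	大于
小于	lt	ArithmeticOperator	低于
等于	eq	ArithmeticOperator
至	range	RangeSeparator	到
患有	suffer	Relation	得了
吃了	take	Relation	服用|吃
检查	have test	Relation	化验了
做了	operate	Relation
入院	in hospital	Relation	住院了
患者	patient	Class	病人
疾病	disease	Class
药品	drug	Class
年龄	age	Property		patient
性别	sex	Property		patient
化验结果	test result	Property		test
结果数值	result value	Property		test
住院天数	stay days	Property		hospitalization
女	female	EnumValue		sex
男	male	EnumValue		sex
偏低	low	EnumValue		test result
正常	normal	EnumValue		test result
偏高	high	EnumValue		test result
岁	age	Unit		age
天	stay days	Unit		stay days
女患者		Word
的		Stopword
是		Stopword
在		Stopword
了		Stopword
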