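# 27 genes of the PIP2-hydrolysis pathway (DAG kinases, DAG lipases, MGLL,
# IP3 receptors, PKC isoforms, RAS guanyl-releasing proteins).
# Approximate GRCh38 spans, 1-based closed intervals; convenience table only.
gene	chrom	start	end	convention
DGKA	12	55927000	56020000	1-based-closed
DGKB	7	14140000	14920000	1-based-closed
DGKD	2	233350000	233470000	1-based-closed
DGKE	17	56800000	56840000	1-based-closed
DGKG	3	186000000	186260000	1-based-closed
DGKH	13	42040000	42260000	1-based-closed
DGKI	7	137360000	137820000	1-based-closed
DGKK	X	50110000	50280000	1-based-closed
DGKQ	4	950000	990000	1-based-closed
DGKZ	11	46320000	46390000	1-based-closed
DAGLA	11	61700000	61780000	1-based-closed
DAGLB	7	6400000	6470000	1-based-closed
MGLL	3	127700000	127850000	1-based-closed
ITPR1	3	4490000	4850000	1-based-closed
ITPR2	12	26330000	26830000	1-based-closed
ITPR3	6	33620000	33700000	1-based-closed
PRKCA	17	66300000	66810000	1-based-closed
PRKCB	16	23840000	24230000	1-based-closed
PRKCD	3	53150000	53200000	1-based-closed
PRKCE	2	45650000	46190000	1-based-closed
PRKCG	19	53870000	53910000	1-based-closed
PRKCH	14	61200000	61450000	1-based-closed
PRKCQ	10	6420000	6580000	1-based-closed
RASGRP1	15	38480000	38560000	1-based-closed
RASGRP2	11	64720000	64760000	1-based-closed
RASGRP3	2	33430000	33560000	1-based-closed
RASGRP4	19	38400000	38430000	1-based-closed
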