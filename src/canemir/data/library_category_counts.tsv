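# Example per-category accounting of one sugarcane sRNA library (unique tags
# and total reads per annotation class), used as a worked example for the
# CategorySummary arithmetic.
library	category	unique	total
HTI	miRNA	33295	2568341
HTI	rRNA	57826	690977
HTI	siRNA	99469	640673
HTI	snRNA	2778	13047
HTI	snoRNA	1457	4727
HTI	tRNA	15783	1058986
HTI	Unannotated	3660105	7230626
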