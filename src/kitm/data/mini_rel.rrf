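C001|A0001|CUI|IS_A|C005|A0007|CUI|||TOYVOC|IS_A||||N|
C006|A0009|CUI|IS_A|C005|A0007|CUI|||TOYVOC|IS_A||||N|
C005|A0007|CUI|IS_A|C004|A0006|CUI|||TOYVOC|IS_A||||N|
C004|A0006|CUI|IS_A|C011|A0016|CUI|||TOYVOC|IS_A||||N|
C010|A0014|CUI|IS_A|C004|A0006|CUI|||TOYVOC|IS_A||||N|
C002|A0003|CUI|IS_A|C012|A0017|CUI|||TOYVOC|IS_A||||N|
C003|A0005|CUI|IS_A|C012|A0017|CUI|||TOYVOC|IS_A||||N|
C007|A0010|CUI|IS_A|C012|A0017|CUI|||TOYVOC|IS_A||||N|
C008|A0011|CUI|IS_A|C012|A0017|CUI|||TOYVOC|IS_A||||N|
C009|A0012|CUI|IS_A|C002|A0003|CUI|||TOYVOC|IS_A||||N|
C001|A0001|CUI|may_treat|C002|A0003|CUI|||TOYVOC|may_treat||||N|
C001|A0001|CUI|may_treat|C007|A0010|CUI|||TOYVOC|may_treat||||N|
C006|A0009|CUI|may_treat|C008|A0011|CUI|||TOYVOC|may_treat||||N|
C010|A0014|CUI|may_treat|C003|A0005|CUI|||TOYVOC|may_treat||||N|
C001|A0001|CUI|may_prevent|C009|A0012|CUI|||TOYVOC|may_prevent||||N|
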