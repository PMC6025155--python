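C001|ENG|P|L0001|PF|S0001|Y|A0001|||C001|TOYVOC|PT|001|aspirin|0|N|
C001|ENG|S|L0002|VO|S0002|N|A0002|||C001|TOYVOC|SY|001|acetylsalicylic acid|0|N|
C002|ENG|P|L0003|PF|S0003|Y|A0003|||C002|TOYVOC|PT|002|headache|0|N|
C002|ENG|S|L0004|VO|S0004|N|A0004|||C002|TOYVOC|SY|002|head ache|0|N|
C003|ENG|P|L0005|PF|S0005|Y|A0005|||C003|TOYVOC|PT|003|pain|0|N|
C004|ENG|P|L0006|PF|S0006|Y|A0006|||C004|TOYVOC|PT|004|analgesic|0|N|
C005|ENG|P|L0007|PF|S0007|Y|A0007|||C005|TOYVOC|PT|005|nsaid|0|N|
C005|ENG|S|L0008|VO|S0008|N|A0008|||C005|TOYVOC|SY|005|non-steroidal anti-inflammatory drug|0|N|
C006|ENG|P|L0009|PF|S0009|Y|A0009|||C006|TOYVOC|PT|006|ibuprofen|0|N|
C007|ENG|P|L0010|PF|S0010|Y|A0010|||C007|TOYVOC|PT|007|fever|0|N|
C008|ENG|P|L0011|PF|S0011|Y|A0011|||C008|TOYVOC|PT|008|inflammation|0|N|
C009|ENG|P|L0012|PF|S0012|Y|A0012|||C009|TOYVOC|PT|009|migraine|0|N|
C009|ENG|S|L0013|VO|S0013|N|A0013|||C009|TOYVOC|SY|009|migraine headache|0|N|
C010|ENG|P|L0014|PF|S0014|Y|A0014|||C010|TOYVOC|PT|010|paracetamol|0|N|
C010|ENG|S|L0015|VO|S0015|N|A0015|||C010|TOYVOC|SY|010|acetaminophen|0|N|
C011|ENG|P|L0016|PF|S0016|Y|A0016|||C011|TOYVOC|PT|011|drug|0|N|
C012|ENG|P|L0017|PF|S0017|Y|A0017|||C012|TOYVOC|PT|012|condition|0|N|
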