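# Default trigger-keyword lexicon for stage-1 combination detection.
# All lists are user-editable; the defaults cover the common classical
# constructions plus ASCII equivalents so the engine also works on
# transliterated or placeholder corpora.

# keywords announcing herbs added to a basic formula
add_keywords: ["加", "入", "加用", "再加", "add", "ADD"]
# keywords announcing herbs removed from a basic formula
remove_keywords: ["去", "减", "除", "去掉", "remove", "REMOVE"]
# keywords announcing a formula joined to the basic formula
join_keywords: ["合", "合用", "并用", "join", "JOIN"]
# two-capture regexes: group 1 = herbs added, group 2 = herbs removed
replace_patterns:
  - "以(.+?)易(.+?)[，。；]"
  - "用(.+?)代(.+?)[，。；]"
  - "REPLACE (.+?) FOR (.+?)[，。；,;.]"
# punctuation treated as transparent between combination members
delimiters: "，。、；：﹑·,;:. \t"
# connector words allowed (in full) between combination members
conjunctions: ["及", "与", "并", "兼", "and"]
# dose expression immediately following a herb mention
dosage_pattern: "[一二三四五六七八九十百两半0-9]+[钱两分斤克枚片gG]"
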