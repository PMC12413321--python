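# Questionnaire/template line patterns stripped before matching.
# One regular expression per line; a note line is removed when the pattern
# is found anywhere in it. Lines starting with '#' are comments.
(?i)^\s*transportation needs?\s*[:?]
(?i)^\s*do you have (reliable |adequate )?transportation
(?i)^\s*(trouble|problems?) (getting|with) transportation.*[:?]
(?i)^\s*social (history|needs?) (questionnaire|screening)
(?i)^\s*in the past (12 months|year).*transportation
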