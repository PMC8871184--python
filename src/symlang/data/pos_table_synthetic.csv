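category,probability,placeholder
noun,0.28,time
verb,0.19,said
preposition,0.13,of
determiner,0.12,the
pronoun,0.09,he
adjective,0.08,new
adverb,0.06,not
conjunction,0.05,and
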