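# Open pronoun lexicon: "category: word word ..." per line.
# Six disjoint categories; the total-pronoun feature is their sum.
first_singular: i me my mine myself im i'm i've i'll i'd
first_plural: we us our ours ourselves we're we've we'll let's lets
second: you your yours yourself yourselves you're you've you'll u ur
third_singular: she he her him his hers herself himself she's he's
third_plural: they them their theirs themselves they're they've they'll
impersonal: it its it's this that these those what which something anything nothing everything someone anyone everyone somebody anybody nobody everybody
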