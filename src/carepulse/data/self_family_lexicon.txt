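# Words counted as a reference to the poster or a family member (binary feature).
i
i'm
i've
i'd
me
my
mine
myself
mom
mum
mother
dad
father
sister
brother
son
daughter
wife
husband
grandma
grandpa
grandmother
grandfather
aunt
uncle
cousin
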