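# Library of non-geographic profile "locations" frequently used on social media.
# Exact entries, one per line, matched case-insensitively after normalization.
# Lines starting with 'pattern:' are treated as regular expressions.
in your heart
with aliens
under your bed
everywhere
nowhere
somewhere
earth
planet earth
mother earth
the moon
moon
mars
outer space
space
the internet
internet
worldwide
world wide
global
the universe
universe
hogwarts
narnia
neverland
wonderland
gotham
westeros
middle earth
atlantis
heaven
hell
paradise
my own world
your moms house
behind you
right behind you
here
over there
home
lost
wandering
dreamland
la la la land
pattern:^[0-9\s]*$
pattern:^(in|on|at)\s+(my|your|the)\s+\w+$
pattern:^follow\b
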