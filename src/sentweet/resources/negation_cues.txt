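not
no
never
n't
nt
without
cannot
none
nobody
nothing
neither
nor
hardly
barely
scarcely
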