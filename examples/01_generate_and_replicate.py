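"""Generate a mother modification pattern and replicate it once.

Draws a 60-nucleosome H3K27me3-like pattern from the two-state Markov
chain at alpha = beta = 0.9 (mean island length 10 nucleosomes) and
passes it through the replication channel, which deletes each mark with
probability one half.
"""

from epifill import ChannelSpec, MarkovParams, ber, generate_mother, replicate

params = MarkovParams(alpha=0.9, beta=0.9)
mother = generate_mother(params, n=60, seed=7)
daughter = replicate(mother, ChannelSpec(retention=0.5), seed=8)

show = lambda s: "".join(str(int(v)) for v in s)
print("mother  :", show(mother))
print("daughter:", show(daughter))
print(f"raw error: {ber(mother, daughter):.3f}")
# The daughter keeps roughly half the marks; the raw error equals the
# fraction of modified nucleosomes that lost their mark (~0.25 here,
# since about half the positions are modified).
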