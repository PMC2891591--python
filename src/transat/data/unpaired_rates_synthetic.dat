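# Synthetic reversible 4-state substitution model for UNPAIRED RNA alignment
# columns.  Not transcribed from any published table: constructed GTR-style
# as Q[a,b] = s[a,b] * pi[b] with transition/transversion exchangeability
# ratio 4, equilibrium frequencies set to a typical A-rich loop composition,
# and the matrix scaled to one expected substitution per site per unit time.
# Layout: state order line, then the rate matrix Q (rows sum to 0), then the
# equilibrium frequency vector pi.
A C G U
-0.87059479036077436 0.11840089148906532 0.55718066583089565 0.19501323304081347
0.2437665413010168 -1.1631146399219947 0.13929516645772391 0.78005293216325389
0.97506616520406719 0.11840089148906532 -1.288480289733946 0.19501323304081347
0.2437665413010168 0.4736035659562613 0.13929516645772391 -0.85666527371500201
0.34999999999999998 0.17000000000000001 0.20000000000000001 0.28000000000000003
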