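# Synthetic reversible 16-state substitution model for BASE-PAIRED RNA
# alignment column pairs (ordered dinucleotide states, row-major AA..UU).
# Not transcribed from any published table: constructed GTR-style as
# Q[a,b] = s[a,b] * pi[b].  Equilibrium mass is concentrated on the six
# consensus pairs (AU/UA 0.17, GC/CG 0.24, GU/UG 0.05; 0.008 per
# non-consensus state).  Single-base changes inherit the 4-state
# exchangeabilities; double (compensatory) changes between consensus pairs
# have exchangeability 1.5, other double changes 0.02.  Scaled to one
# expected substitution event per pair per unit time.
# Layout: state order line, then Q (rows sum to 0), then pi.
AA AC AG AU CA CC CG CU GA GC GG GU UA UC UG UU
-0.32617758254193779 0.0060347378823670268 0.024138951529468107 0.12823818000029932 0.0060347378823670268 0.00012069475764734054 0.0036208427294202156 0.00012069475764734054 0.024138951529468107 0.0036208427294202156 0.00012069475764734054 0.00075434223529587834 0.12823818000029932 0.00012069475764734054 0.00075434223529587834 0.00012069475764734054
0.0060347378823670268 -1.269557982002963 0.0060347378823670268 0.51295272000119729 0.00012069475764734054 0.0060347378823670268 0.0036208427294202156 0.00012069475764734054 0.00012069475764734054 0.72416854588404311 0.00012069475764734054 0.00075434223529587834 0.0025647636000059866 0.0060347378823670268 0.00075434223529587834 0.00012069475764734054
0.024138951529468107 0.0060347378823670268 -0.40897418628801335 0.12823818000029932 0.00012069475764734054 0.00012069475764734054 0.18104213647101078 0.00012069475764734054 0.00012069475764734054 0.0036208427294202156 0.024138951529468107 0.00075434223529587834 0.0025647636000059866 0.00012069475764734054 0.03771711176479392 0.00012069475764734054
0.0060347378823670268 0.024138951529468107 0.0060347378823670268 -0.99180917096702081 0.00012069475764734054 0.00012069475764734054 0.27156320470651618 0.0060347378823670268 0.00012069475764734054 0.27156320470651618 0.00012069475764734054 0.15086844705917568 0.19235727000044897 0.00012069475764734054 0.05657566764719088 0.0060347378823670268
0.0060347378823670268 0.00012069475764734054 0.00012069475764734054 0.0025647636000059866 -1.2695579820029632 0.0060347378823670268 0.72416854588404311 0.0060347378823670268 0.0060347378823670268 0.0036208427294202156 0.00012069475764734054 0.00075434223529587834 0.51295272000119729 0.00012069475764734054 0.00075434223529587834 0.00012069475764734054
0.00012069475764734054 0.0060347378823670268 0.00012069475764734054 0.0025647636000059866 0.0060347378823670268 -0.42967333722453227 0.18104213647101078 0.024138951529468107 0.00012069475764734054 0.18104213647101078 0.00012069475764734054 0.00075434223529587834 0.0025647636000059866 0.024138951529468107 0.00075434223529587834 0.00012069475764734054
0.00012069475764734054 0.00012069475764734054 0.0060347378823670268 0.19235727000044897 0.024138951529468107 0.0060347378823670268 -0.91260323626095352 0.0060347378823670268 0.00012069475764734054 0.27156320470651618 0.0060347378823670268 0.05657566764719088 0.19235727000044897 0.00012069475764734054 0.15086844705917568 0.00012069475764734054
0.00012069475764734054 0.00012069475764734054 0.00012069475764734054 0.12823818000029932 0.0060347378823670268 0.024138951529468107 0.18104213647101078 -0.40897418628801335 0.00012069475764734054 0.0036208427294202156 0.00012069475764734054 0.03771711176479392 0.0025647636000059866 0.00012069475764734054 0.00075434223529587834 0.024138951529468107
0.024138951529468107 0.00012069475764734054 0.00012069475764734054 0.0025647636000059866 0.0060347378823670268 0.00012069475764734054 0.0036208427294202156 0.00012069475764734054 -0.40897418628801335 0.18104213647101078 0.024138951529468107 0.03771711176479392 0.12823818000029932 0.00012069475764734054 0.00075434223529587834 0.00012069475764734054
0.00012069475764734054 0.024138951529468107 0.00012069475764734054 0.19235727000044897 0.00012069475764734054 0.0060347378823670268 0.27156320470651618 0.00012069475764734054 0.0060347378823670268 -0.91260323626095352 0.0060347378823670268 0.15086844705917568 0.19235727000044897 0.0060347378823670268 0.05657566764719088 0.00012069475764734054
0.00012069475764734054 0.00012069475764734054 0.024138951529468107 0.0025647636000059866 0.00012069475764734054 0.00012069475764734054 0.18104213647101078 0.00012069475764734054 0.024138951529468107 0.18104213647101078 -0.49177079003408902 0.03771711176479392 0.0025647636000059866 0.00012069475764734054 0.03771711176479392 0.00012069475764734054
0.00012069475764734054 0.00012069475764734054 0.00012069475764734054 0.51295272000119729 0.00012069475764734054 0.00012069475764734054 0.27156320470651618 0.0060347378823670268 0.0060347378823670268 0.72416854588404311 0.0060347378823670268 -1.7824805283147487 0.19235727000044897 0.00012069475764734054 0.05657566764719088 0.0060347378823670268
0.0060347378823670268 0.00012069475764734054 0.00012069475764734054 0.19235727000044897 0.024138951529468107 0.00012069475764734054 0.27156320470651618 0.00012069475764734054 0.0060347378823670268 0.27156320470651618 0.00012069475764734054 0.05657566764719088 -0.99180917096702081 0.0060347378823670268 0.15086844705917568 0.0060347378823670268
0.00012069475764734054 0.0060347378823670268 0.00012069475764734054 0.0025647636000059866 0.00012069475764734054 0.024138951529468107 0.0036208427294202156 0.00012069475764734054 0.00012069475764734054 0.18104213647101078 0.00012069475764734054 0.00075434223529587834 0.12823818000029932 -0.40897418628801335 0.03771711176479392 0.024138951529468107
0.00012069475764734054 0.00012069475764734054 0.0060347378823670268 0.19235727000044897 0.00012069475764734054 0.00012069475764734054 0.72416854588404311 0.00012069475764734054 0.00012069475764734054 0.27156320470651618 0.0060347378823670268 0.05657566764719088 0.51295272000119729 0.0060347378823670268 -1.7824805283147487 0.0060347378823670268
0.00012069475764734054 0.00012069475764734054 0.00012069475764734054 0.12823818000029932 0.00012069475764734054 0.00012069475764734054 0.0036208427294202156 0.024138951529468107 0.00012069475764734054 0.0036208427294202156 0.00012069475764734054 0.03771711176479392 0.12823818000029932 0.024138951529468107 0.03771711176479392 -0.38827503535149455
0.0080000000000000002 0.0080000000000000002 0.0080000000000000002 0.17000000000000001 0.0080000000000000002 0.0080000000000000002 0.23999999999999999 0.0080000000000000002 0.0080000000000000002 0.23999999999999999 0.0080000000000000002 0.050000000000000003 0.17000000000000001 0.0080000000000000002 0.050000000000000003 0.0080000000000000002
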