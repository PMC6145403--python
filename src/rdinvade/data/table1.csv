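# Reference empirical summary of the 24-population invasion assay:
# per-generation mean (and SE) proportion of adults showing the WT
# phenotype, by sexual-selection regime of the introduced males
# (Monogamy vs Polyandry), generations 2-8. These are published summary
# statistics of real beetle populations, used as a fixture for summary
# and scenario-fit code; they are not recomputable from this package.
generation,monogamy_mean,monogamy_se,polyandry_mean,polyandry_se
2,0.04,0.01,0.06,0.01
3,0.11,0.01,0.20,0.02
4,0.22,0.02,0.49,0.02
5,0.44,0.02,0.79,0.02
6,0.63,0.02,0.84,0.02
7,0.75,0.03,0.90,0.01
8,0.78,0.03,0.94,0.01
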