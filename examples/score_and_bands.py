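"""Score RT-qPCR Ct panels and convert score bands into disease probabilities.

Generates a validation-like cohort (case/control/'possible' labels at 30%
prevalence), computes the four-gene score = -Ct(PLAC8) + Ct(PLA2G7) - Ct(LAMP1)
+ Ct(CEACAM4) per sample, and prints the band table: per-band likelihood ratios
(how many times more likely a score in that band is under sepsis than under
sterile inflammation) and the post-test probabilities they imply at a 30%
pre-test probability. Low bands should drive the sepsis probability toward zero,
high bands toward one.
"""

import septikit as sk

spec = sk.SimSpec(seed=8)
panels, labels = sk.generate_validation_cohort(spec, n_total=345)
scored = sk.score_panels(panels)
print(scored.head(5).to_string())

known = labels.known_status()  # drops diagnostically ambiguous 'possible' samples
ids = [s for s in scored.index if s in known.frame.index]
tab = sk.band_table(scored.loc[ids, "septiscore"], known, pretest=0.30)
print("\nband table (pre-test probability 30%):")
print(tab[["n_controls", "n_cases", "likelihood_ratio",
           "post_test_probability"]].round(3).to_string())

low = tab["post_test_probability"].iloc[0]
print(f"\na score below 4 leaves a sepsis probability of {100 * low:.1f}% "
      f"(NPV {100 * (1 - low):.1f}%)")
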