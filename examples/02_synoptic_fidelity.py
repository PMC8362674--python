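"""Build a synoptic table and read species roles off it.

Shows, for one association, its most faithful species (phi coefficient,
one-sided Fisher p) and the role flags derived from the printed thresholds
(diagnostic phi >= 0.25 with p < 0.001 for associations, constant >= 40 %
frequency, dominant >= 25 % cover in >= 5 % of the unit's plots).
"""

from vegclass import build_synoptic, generate, species_roles

ds = generate(n_per_unit=30, seed=7)
syn = build_synoptic(ds.table, ds.labels)
ranks = {unit: "association" for unit in set(ds.labels.values())}
syn = species_roles(syn, ds.table, ds.labels, ranks=ranks)

unit = "Polygono-Eleocharitetum ovatae"
top = syn.phi[unit].sort_values(ascending=False).head(5)
print(f"most faithful species of {unit}:")
for sp, value in top.items():
    freq = syn.frequency.at[sp, unit]
    p = syn.fisher_p.at[sp, unit]
    roles = ",".join(sorted(syn.roles.at[sp, unit])) or "-"
    print(f"  {sp:28s} phi={value:5.2f}  freq={freq:5.1f}%  p={p:.2e}  [{roles}]")
# Interpretation: the unit's core species head the list with phi near 1 and
# vanishing p; shared background species (e.g. Juncus bufonius) may be
# constant but are never diagnostic.
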