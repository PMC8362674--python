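"""Thin geographically clustered relevés with grid stratified resampling.

Keeps at most three relevés per vegetation unit in every 1.25' x 0.75'
grid cell (about 1.4 x 1.4 km), the standard guard against local
oversampling in vegetation-plot archives.
"""

import dataclasses
import tempfile

from vegclass import GridSpec, export_geojson, generate, stratified_sample
from vegclass.synthetic_data import default_profiles

# tighten the spatial scatter to mimic heavily resurveyed localities
profiles = [dataclasses.replace(p, scatter=0.02) for p in default_profiles()]
ds = generate(profiles, n_per_unit=60, seed=3)
sample = stratified_sample(
    ds.table, ds.labels, GridSpec(1.25, 0.75), per_cell=3, seed=1
)
print(f"relevés before: {len(ds.table)}, after stratification: {len(sample)}")

with tempfile.TemporaryDirectory() as tmp:
    paths = export_geojson(
        sample, {p: ds.labels[p] for p in sample.plot_ids}, tmp
    )
    print(f"wrote {len(paths)} GeoJSON point collections (one per unit)")
# Interpretation: units whose plots pile up near their regional center lose
# plots to the per-cell cap; geographically scattered units keep almost all.
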