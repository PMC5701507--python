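"""Estimate chromosome copy numbers from binned WGS depth.

Simulates Poisson-distributed depth (500 bins per chromosome, 30x diploid
coverage) for an XO karyotype — one X, no Y — and recovers it by anchoring
the pooled autosomal median depth to copy 2.  This is the readout used to
confirm whole-chromosome elimination after editing.
"""

from karyocut import estimate_copy_number
from karyocut.simulate import make_depth_table

karyotype = {f"chr{i}": 2 for i in range(1, 6)} | {"chrX": 1, "chrY": 0}
depth = make_depth_table(karyotype, seed=2024, bins_per_chrom=500, mean_depth=30.0)

profile = estimate_copy_number(depth, autosomes=[f"chr{i}" for i in range(1, 6)])
print(f"autosomal median depth (copy 2 anchor): {profile.autosomal_median:.1f}")
print("chrom   median_depth  copy_raw  copy")
for chrom in karyotype:
    print(f"{chrom:6}  {profile.median_depth[chrom]:>10.1f}  "
          f"{profile.raw[chrom]:>8.3f}  {profile.rounded[chrom]:>4}")
print()
print("chrX rounds to 1 and chrY to 0: the XO (Turner-like) karyotype, with")
print("all autosomes at copy 2.")
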