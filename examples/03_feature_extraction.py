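"""Extract the full multiparametric feature set for one phantom patient.

12 first-order titles x 6 subregions x 4 modalities x 3 voxel sizes = 864,
plus 52 high-order titles (GLCM 22, GLRLM 13, GLSZM 12, NGTDM 5) x 6 x 4
x 36 settings = 44 928, i.e. 45 792 measures per patient.
"""

import mpradiomics as mp

spec = mp.PhantomSpec(n_patients=2, seed=7)
study = mp.generate_phantom(spec, 0)
grid = mp.enumerate_grid()
row = mp.extract_study(study, grid)

n_first = sum("firstorder" in c for c in row.index)
print(f"total measures: {row.size}  (first-order {n_first}, "
      f"high-order {row.size - n_first})")
print(f"missing (empty-subregion) measures: {int(row.isna().sum())}")

print("\na few example measures:")
for col in [
    "T1C_enhancing_firstorder_mean@VS1",
    "T1_whole_tumor_GLCM_IDMN@VS1|Ld|GL128",
    "FLAIR_edema_GLRLM_HGRE@VS2|Uf|GL32",
    "T2_solid_core_GLSZM_GLN@VS1|Eq|GL64",
    "T1_whole_tumor_NGTDM_coarseness@VS3|Uf|GL32",
]:
    print(f"  {col:48s} = {row[col]:.4f}")
print("\ncolumn names read modality_region_family_title@VS|QM|GL, so every "
      "measure records its standardization setting.")
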