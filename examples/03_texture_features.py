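"""Extract the full radiomics panel from a tumor and its habitats.

The default manifest applies 14 filter images (original, LoG at 1-5 mm, 8
wavelet subbands) x 86 intensity/texture features + 14 shape features
= 1218 features per region; with three habitat subregions that is 3654
additional Sub{j}-prefixed columns.
"""

import numpy as np

import habikit as hk

spec = hk.PhantomSpec(n_patients=1, seed=3, tumor_radius_range=(12.0, 14.0))
volumes, _, truth = hk.generate_cohort(spec)
img, msk = volumes[0]

manifest = hk.load_manifest("default")
print(f"manifest '{manifest.name}': {manifest.total_per_region} features "
      f"per region ({len(manifest.filters)} filters x "
      f"{sum(len(v) for v in manifest.families.values())} + "
      f"{len(manifest.shape)} shape)")

whole = hk.extract_region(img, msk, manifest)
print(f"\nwhole tumor: {len(whole)} features, e.g.")
for name in ("original_firstorder_InterquartileRange",
             "log.sigma.4.0.mm.3D_glcm_Idn",
             "wavelet.LHH_glrlm_GrayLevelVariance",
             "original_shape_Sphericity"):
    print(f"  {name} = {whole[name]:.4g}")

hmap = hk.HabitatMap(labels=truth.label_volumes[0].astype(np.int16), k=3,
                     spacing=msk.spacing)
habs = hk.extract_patient(img, msk, hmap, manifest, regions="habitats")
print(f"\nthree habitat subregions: {len(habs)} features "
      f"(3 x {manifest.total_per_region})")
print("  Sub1_original_firstorder_Mean =",
      round(habs["Sub1_original_firstorder_Mean"], 2), "HU (low-HU habitat)")
print("  Sub3_original_firstorder_Mean =",
      round(habs["Sub3_original_firstorder_Mean"], 2), "HU (high-HU habitat)")
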