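"""Generate a small unpaired coronary phantom dataset and describe it.

The phantom generator stands in for clinical OCT/H&E archives: each sample
is a three-layer tissue slab (intima/media/adventitia) rendered either as a
speckled OCT image or as an H&E-coloured image, optionally with lipid or
calcium inclusions and a pixel-level layer mask.
"""

from collections import Counter
from pathlib import Path

from octstain.phantom import PhantomSpec, generate_dataset, load_manifest

out = Path("scratch_examples/phantoms")
spec = PhantomSpec(height=64, width=64)
manifest = generate_dataset(n_normal=12, n_pathological=8, base_spec=spec,
                            labeled_fraction=0.5, seed=7, out_dir=out)
rows = load_manifest(manifest)

domains = Counter(r["domain"] for r in rows)
n_path = sum(r["pathology_label"] for r in rows)
n_masked = sum(bool(r["mask_path"]) for r in rows)
print(f"manifest: {manifest}")
print(f"{len(rows)} samples ({domains['oct']} OCT / {domains['he']} H&E), "
      f"{n_path} pathological, {n_masked} with pixel masks")
print("Each row is one image in one domain; the two domains come from "
      "independent geometries, so the dataset is unpaired by construction.")
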