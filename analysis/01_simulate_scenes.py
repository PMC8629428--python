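"""Generate the synthetic study conditions.

Three two-channel membrane-sheet conditions are rendered with known ground
truth, emulating the experimental contrast between a control (endogenous
cluster density, moderate crowd recruitment), a syntaxin-overexpression-like
condition (3x clusters, strong recruitment, epitope shielding near cluster
cores), and a SNARE-deleted-like condition (3x clusters but no recruitment
and no shielding).  Images go to scratch/ (bulky binaries); per-condition
metadata and the manifest go to results/.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from memcrowd import RenderSpec, SceneSpec, simulate_scene
from memcrowd.pipeline import save_image

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scenes"
RESULTS = ROOT / "results"

CONDITIONS = {
    "control": dict(coupling_p=0.5, cluster_density_per_um2=11.0, shield_p=0.0),
    "stx_full": dict(coupling_p=0.9, cluster_density_per_um2=33.0, shield_p=0.4),
    "stx_ds": dict(coupling_p=0.0, cluster_density_per_um2=33.0, shield_p=0.0),
}

N_SHEETS = 4  # sheets (fields of view) per condition
WINDOW_UM = (4.0, 4.0)


def main(seed: int = 7) -> None:
    RESULTS.mkdir(exist_ok=True)
    manifest = []
    for name, params in CONDITIONS.items():
        shield_p = params.pop("shield_p")
        for rep in range(N_SHEETS):
            spec = SceneSpec(window_um=WINDOW_UM, seed=seed + 100 * rep, **params)
            render = RenderSpec(shield_p=shield_p)
            scene = simulate_scene(spec, render)
            d = SCRATCH / name / f"sheet{rep}"
            d.mkdir(parents=True, exist_ok=True)
            save_image(scene.image_clusters, d / "clusters.tif")
            save_image(scene.image_crowds, d / "crowds.tif")
            (d / "metadata.json").write_text(
                json.dumps({"scene": asdict(spec), "render": asdict(render), **scene.meta})
            )
            manifest.append(
                {
                    "condition": name,
                    "sheet": rep,
                    "clusters_tif": str(d / "clusters.tif"),
                    "crowds_tif": str(d / "crowds.tif"),
                    "n_clusters_true": scene.meta["n_clusters"],
                    "n_crowds_true": scene.meta["n_crowds"],
                }
            )
        params["shield_p"] = shield_p
    df = pd.DataFrame(manifest)
    df.to_csv(RESULTS / "scene_manifest.csv", index=False)
    print(f"rendered {len(df)} sheets over {df['condition'].nunique()} conditions")
    print(df.groupby("condition")[["n_clusters_true", "n_crowds_true"]].mean())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
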