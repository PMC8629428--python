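"""Measure cluster/crowd metrics per condition and compare to control.

Runs the full measurement pipeline (maxima detection, linescan sizing,
density, rSDM, PCC + flipped control) over the scenes rendered by
01_simulate_scenes.py, then expresses each condition as percent of the
control mean, mirroring how condition panels are usually summarized.
"""

from pathlib import Path

import pandas as pd

from memcrowd.pipeline import ImageEntry, RunConfig, condition_compare, run_analysis

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    manifest = pd.read_csv(RESULTS / "scene_manifest.csv")
    bundles = {}
    for name, grp in manifest.groupby("condition"):
        cfg = RunConfig(
            images=[
                ImageEntry(
                    image_id=f"{name}_s{r.sheet}",
                    path_a=r.clusters_tif,
                    path_b=r.crowds_tif,
                    channel_a="clusters",
                    channel_b="crowds",
                    background_a=5.0,
                    background_b=5.0,
                )
                for r in grp.itertuples()
            ],
            csr_replicates=20,
            seed=11,
            output_dir=str(RESULTS / "runs" / name),
        )
        bundles[name] = run_analysis(cfg)

    rows = []
    for metric, channel in [
        ("density_per_um2", "clusters"),
        ("mean_size_nm", "clusters"),
        ("mean_intensity", "clusters"),
        ("rsdm", "crowds"),
        ("pcc", "crowds"),
    ]:
        for cond in ("stx_full", "stx_ds"):
            res = condition_compare(bundles["control"], bundles[cond], metric, channel)
            rows.append({"condition": cond, "channel": channel, **res})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "condition_compare.csv", index=False)
    show = table[["condition", "channel", "metric", "control_mean", "treated_mean",
                  "treated_pct", "p"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(
        "\nhigher cluster density/intensity in both overexpression-like conditions;"
        "\ncrowd rSDM and PCC stay high while recruitment is present (control,"
        "\nstx_full) and collapse when the coupling is removed (stx_ds)"
    )


if __name__ == "__main__":
    main()
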