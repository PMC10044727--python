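"""Run the full 14-species dispersal experiment at the study's release
scheme: 1000 particles per occupied MPA (217,000 in total), species-specific
spawning dates and living depths, 15% daily mortality, master seed 0.

Found: daily mortality dominates fate (few survivors beyond ~20-day PLDs)
and most arrivals are origin-MPA presence; alongshore transport exports the
rest, southward for winter/spring spawners and northward for summer
spawners riding the counter-current.  Full outputs (per-species matrices,
arrivals)
land in scratch/full_run/; the small aggregate tables are copied to
results/ for inspection and for the downstream analysis scripts.
"""

import shutil
from pathlib import Path

from larvanet import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]

KEEP = [
    "aggregate_c_matrix.csv",
    "aggregate_recruitment.csv",
    "aggregate_edges.csv",
    "node_metrics.csv",
    "network_report.json",
    "network_report.txt",
    "manifest.json",
]


def main():
    run_dir = ROOT / "scratch" / "full_run"
    cfg = RunConfig(particles_per_point=1000, seed=0,
                    output_dir=str(run_dir))
    manifest = run_pipeline(cfg)
    print(f"released {manifest['total_released']} particles over "
          f"{len(manifest['species'])} species")
    for name, acc in manifest["accounting"].items():
        print(f"  {name}: released={acc['released']} alive={acc['alive']} "
              f"stranded={acc['stranded']} exited={acc['dead_exit']} "
              f"arrivals={acc['arrival_records']}")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in KEEP:
        shutil.copy(run_dir / name, results / name)
    print(f"aggregate tables copied to results/ "
          f"({manifest['network']['n_edges']} network edges, "
          f"{len(manifest['network']['isolated'])} isolated MPAs)")


if __name__ == "__main__":
    main()
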