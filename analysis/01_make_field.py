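"""Generate the synthetic seasonal coastal-current field and report its
qualitative circulation diagnostics.

Found: with the default configuration (0.15 m/s jet core, 0.8° width,
November-April southward regime, surface-to-100 m attenuation 1.0 -> 0.4)
the surface jet peaks in the 0.1-0.2 m/s band, the mean alongshore flow in
the jet reverses sign between January and July, and layer-mean speed decays
monotonically with depth.  Writes the field to scratch/field.nc and the
diagnostics to results/field_diagnostics.json.
"""

import json
from pathlib import Path

import numpy as np

from larvanet import SyntheticOceanConfig, generate_field

ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = SyntheticOceanConfig()
    field = generate_field(cfg)
    (ROOT / "scratch").mkdir(exist_ok=True)
    field.save(ROOT / "scratch" / "field.nc")

    wet = ~field.land_mask
    months = field.time_axis.astype("datetime64[M]").astype(int) % 12 + 1
    jan = int(np.where(months == 1)[0][0])
    jul = int(np.where(months == 7)[0][0])
    speed = np.hypot(field.u, field.v)
    diagnostics = {
        "grid_shape": list(field.u.shape),
        "max_surface_speed_ms": float(speed[:, 0][:, wet].max()),
        "jan_mean_v_surface_ms": float(field.v[jan, 0][wet].mean()),
        "jul_mean_v_surface_ms": float(field.v[jul, 0][wet].mean()),
        "layer_mean_speed_ms": [float(speed[jan, k][wet].mean())
                                for k in range(field.depth_axis.size)],
        "land_fraction": float(field.land_mask.mean()),
    }
    out = ROOT / "results" / "field_diagnostics.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(diagnostics, indent=2) + "\n")
    print(f"wrote scratch/field.nc and {out.relative_to(ROOT)}")
    print(f"max surface speed: {diagnostics['max_surface_speed_ms']:.3f} m/s")
    print(f"mean surface v (jet month Jan vs Jul): "
          f"{diagnostics['jan_mean_v_surface_ms']:+.4f} vs "
          f"{diagnostics['jul_mean_v_surface_ms']:+.4f} m/s")


if __name__ == "__main__":
    main()
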