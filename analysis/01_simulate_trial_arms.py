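"""Simulate the meta-analytic trial-arm datasets.

Generates one Pearl-Index and one ovulation-rate dataset with the
structure the pooled analysis assumes: 20 arms per drug (LNG, DRSP) on an
even log10-pmol/L exposure grid over [1.8, 5.2], 450 subjects per arm
(80 arms x 450 ~ the 36,040 women of the real meta-analysis), additive
arm-level noise with variance sigma^2/n at the published per-drug
residual scales.  Writes results/arms_pi.csv and results/arms_or.csv.
"""

import numpy as np

from cocpd.io import write_arms
from cocpd.simulate import SynthDesign, generate_arms, published_or_params, published_pi_params
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_PER_ARM = 450
GRID = np.linspace(1.8, 5.2, 20)

for truth, seed, name in [
    (published_pi_params(), 101, "arms_pi.csv"),
    (published_or_params(), 102, "arms_or.csv"),
]:
    design = SynthDesign(
        true_params=truth,
        exposure_grid={d: GRID for d in truth.drugs},
        n_per_arm=N_PER_ARM,
        seed=seed,
    )
    arms = generate_arms(design)
    write_arms(arms, OUT / name)
    obs = np.array([a.observed for a in arms])
    print(
        f"{truth.endpoint.value}: {len(arms)} arms, {len(arms) * N_PER_ARM} subjects, "
        f"observed range {obs.min():.3f} to {obs.max():.3f} -> results/{name}"
    )
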