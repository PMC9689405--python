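"""Multi-reader measurement-study simulator.

Generates long-format measurement tables under the crossed random-effects
model used for the reliability analysis:

    y_{p,r,k} = μ + x_p'β + a_p + b_r + c_{p,k} + ε_{p,r,k}

with independent zero-mean normal patient (a), reader (b), occasion (c, a
patient×replicate effect shared by all readers — the re-presented radiograph)
and residual (ε) components.  Mirrors the study design in which every
patient is read once by every reader and a small subset of patients is read
three times by everyone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReaderSimSpec", "simulate_reader_study"]

TABLE_COLUMNS = [
    "patient_id",
    "reader_id",
    "replicate",
    "side",
    "metric",
    "value",
    "age",
    "sex",
    "foi",
    "noise",
]


@dataclass
class ReaderSimSpec:
    """Design and variance parameters of a simulated reader study.

    Defaults mirror the emulated study: 78 patients, 5 readers, 5 patients
    re-read 3 times by everyone.  Variances are in squared measurement
    units (deg² for angles).  ``fixed_effects`` maps covariate name
    (age/sex/foi/noise) to its slope; covariates are generated per patient.
    """

    n_patients: int = 78
    n_readers: int = 5
    n_replicate_patients: int = 5
    n_replicates: int = 3
    grand_mean: float = 25.43
    var_patient: float = 39.46
    var_reader: float = 11.88
    var_repeat: float = 7.44
    var_residual: float = 17.80
    fixed_effects: dict = field(default_factory=dict)
    metric: str = "lcea"
    side: str = "right"
    seed: int = 0

    def __post_init__(self):
        for name in ("var_patient", "var_reader", "var_repeat", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_patients", "n_readers", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not 0 <= self.n_replicate_patients <= self.n_patients:
            raise ValueError("n_replicate_patients must be between 0 and n_patients")
        unknown = set(self.fixed_effects) - {"age", "sex", "foi", "noise"}
        if unknown:
            raise ValueError(f"unknown fixed-effect covariates: {sorted(unknown)}")


def simulate_reader_study(spec: ReaderSimSpec, truths: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate a reader study; returns a long-format measurement table.

    ``truths`` optionally fixes the per-patient true values μ + a_p (length
    ``n_patients``); otherwise patient effects are drawn N(0, var_patient).
    The first ``n_replicate_patients`` patients receive ``n_replicates``
    occasions, each read by every reader; all others a single occasion.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    P, R = spec.n_patients, spec.n_readers

    age = rng.uniform(18.0, 91.0, P)
    sex = rng.integers(0, 2, P).astype(float)
    foi = rng.normal(1.0, 0.05, P)
    noise = rng.normal(0.0, 1.0, P)
    covars = {"age": age, "sex": sex, "foi": foi, "noise": noise}
    fixed_part = np.zeros(P)
    for name, beta in spec.fixed_effects.items():
        fixed_part += beta * covars[name]

    if truths is not None:
        truths = np.asarray(truths, dtype=float)
        if truths.shape != (P,):
            raise ValueError(f"truths must have length n_patients={P}")
        patient_level = truths
    else:
        patient_level = spec.grand_mean + rng.normal(0.0, np.sqrt(spec.var_patient), P)
    reader_eff = rng.normal(0.0, np.sqrt(spec.var_reader), R)

    rows = []
    for p in range(P):
        n_occ = spec.n_replicates if p < spec.n_replicate_patients else 1
        occ_eff = rng.normal(0.0, np.sqrt(spec.var_repeat), n_occ)
        for k in range(n_occ):
            eps = rng.normal(0.0, np.sqrt(spec.var_residual), R)
            for r in range(R):
                rows.append(
                    (
                        f"P{p:04d}",
                        f"R{r:02d}",
                        k + 1,
                        spec.side,
                        spec.metric,
                        patient_level[p] + fixed_part[p] + reader_eff[r] + occ_eff[k] + eps[r],
                        age[p],
                        sex[p],
                        foi[p],
                        noise[p],
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
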