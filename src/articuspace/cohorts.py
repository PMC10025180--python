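"""Synthetic cohort generation with the statistical structure of the
reference groups.

Per-subject, per-joint morphometry values are drawn from the configured
group distributions (normal, truncated below at 0 by rejection for
widths, volumes and other nonnegative quantities), so downstream
statistics can be exercised at any sample size with known generating
parameters. Within-subject correlation between joints is not modeled
unless a correlation coefficient is supplied: the reference tables
publish no covariance, and an explicit exchangeable correlation is the
one extra knob offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference_cohorts as ref

__all__ = ["GroupParams", "CohortParams", "synthesize_cohort"]

#: Columns always truncated at zero (physically nonnegative).
_NONNEGATIVE = ("jsv_mm3", "jsw_mm", "jsw_min_mm", "jsw_max_mm", "jsw_as",
                "jsw_sd_mm", "age", "bmi", "height_cm")


@dataclass
class GroupParams:
    """Generating parameters of one cohort group.

    ``morphometry`` maps joint -> parameter -> (mean, sd);
    ``demographics`` maps field -> (mean, sd).
    """

    name: str
    n: int
    sex: str | None = None
    demographics: dict[str, tuple[float, float]] = field(default_factory=dict)
    morphometry: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for table in [self.demographics, *self.morphometry.values()]:
            for key, (_, sd) in table.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {key}")
        params = None
        for joint, tab in self.morphometry.items():
            if params is None:
                params = set(tab)
            elif set(tab) != params:
                raise ValueError(f"incomplete parameter set for joint {joint}")


@dataclass
class CohortParams:
    """Parameters of a full synthetic cohort."""

    groups: list[GroupParams]
    seed: int = 0
    joint_correlation: float = 0.0  # exchangeable between-joint correlation

    @classmethod
    def from_reference(
        cls,
        table: dict | None = None,
        n_override: int | None = None,
        seed: int = 0,
        groups: list[str] | None = None,
    ) -> "CohortParams":
        """Build params from one of the published reference tables
        (defaults to the sex-stratified main cohort)."""
        table = table if table is not None else ref.HH_COHORT
        gps = []
        for name, entry in table.items():
            if groups is not None and name not in groups:
                continue
            morpho = {k: v for k, v in entry.items() if k.startswith("MCP")}
            gps.append(
                GroupParams(
                    name=name,
                    n=n_override if n_override is not None else entry["n"],
                    sex=entry.get("sex"),
                    demographics=entry.get("demographics", {}),
                    morphometry=morpho,
                )
            )
        return cls(groups=gps, seed=seed)


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float, n: int,
                    nonnegative: bool) -> np.ndarray:
    """Normal draws; rejection below 0 for nonnegative quantities."""
    if sd == 0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, size=n)
    if nonnegative:
        bad = out < 0
        # Rejection keeps the realized mean/SD near nominal for the
        # parameter ranges used (truncation mass is small there).
        while bad.any():
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = out < 0
    return out


def synthesize_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a cohort table: one row per subject x joint.

    Columns: subject_id, group, sex, the demographic fields, joint, the
    six morphometry parameters, and ``ankylotic`` (always False for
    synthetic subjects). Identical params + seed give identical tables.
    """
    rng = np.random.default_rng(params.seed)
    rho = params.joint_correlation
    if not 0.0 <= rho < 1.0:
        raise ValueError("joint_correlation must lie in [0, 1)")
    rows = []
    for gp in params.groups:
        if not gp.morphometry and gp.n > 0:
            raise ValueError(f"missing group x joint parameters for {gp.name}")
        demo = {
            k: _draw_truncated(rng, m, sd, gp.n, k in _NONNEGATIVE)
            for k, (m, sd) in gp.demographics.items()
        }
        sexes = (
            np.full(gp.n, gp.sex)
            if gp.sex is not None
            else rng.choice(["M", "F"], size=gp.n)
        )
        # Optional exchangeable correlation via a shared subject factor:
        # z_joint = sqrt(rho) * z_subject + sqrt(1-rho) * z_indep.
        shared = rng.standard_normal((gp.n, len(ref.MORPHOMETRY_PARAMS)))
        for joint, tab in sorted(gp.morphometry.items()):
            vals = {}
            for ip, p in enumerate(ref.MORPHOMETRY_PARAMS):
                if p not in tab:
                    continue
                m, sd = tab[p]
                if rho > 0 and sd > 0:
                    z = np.sqrt(rho) * shared[:, ip] + np.sqrt(1 - rho) * rng.standard_normal(gp.n)
                    v = m + sd * z
                    bad = v < 0
                    while bad.any():
                        v[bad] = m + sd * rng.standard_normal(int(bad.sum()))
                        bad = v < 0
                    vals[p] = v
                else:
                    vals[p] = _draw_truncated(rng, m, sd, gp.n, p in _NONNEGATIVE)
            for i in range(gp.n):
                row = {
                    "subject_id": f"{gp.name}-{i:05d}",
                    "group": gp.name,
                    "sex": sexes[i],
                    "joint": joint,
                    "ankylotic": False,
                }
                row.update({k: demo[k][i] for k in demo})
                row.update({p: vals[p][i] for p in vals})
                rows.append(row)
    if not rows:
        cols = ["subject_id", "group", "sex", "joint", "ankylotic",
                *ref.MORPHOMETRY_PARAMS]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
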