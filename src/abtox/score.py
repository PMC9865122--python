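"""Per-strain Gal/Glu growth ratios.

The screen's toxicity statistic is the ratio of the induced (galactose,
Aβ on) colony size at day d ∈ {3, 4, 5} over the uninduced (glucose,
Aβ off) size at day 3:

    r_d = I_d / U_3        (per replicate)

Sizes below the detection threshold τ are set to 0 before dividing; a
replicate whose uninduced day-3 size is itself below τ is unevaluable
(glucose-deficiency candidate) rather than a division by zero.  The
strain-level aggregate is the arithmetic mean of the finite replicate
ratios (geometric mean available), and a day counts as "zero" for a
strain only when the induced colony is below τ in every replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CONDITION_INDUCED, CONDITION_UNINDUCED

__all__ = ["ScoreResult", "compute_growth_ratios", "default_tau"]

TAU_MEDIAN_FRACTION = 0.05  # τ = 5% of plate-wide median uninduced day-3 size


@dataclass
class ScoreResult:
    """Replicate-level and strain-level growth-ratio tables.

    ``replicates``: strain, replicate, plate and r_d / below-τ flags
    per induced day plus the uninduced below-τ flag.
    ``strains``: per-strain aggregates r_d, all-replicate zero flags
    ``zero_d{d}``, the observed glucose-deficiency flag, and replicate
    counts.  ``warnings`` records strains excluded for missing data.
    """

    replicates: pd.DataFrame
    strains: pd.DataFrame
    tau: dict[int, float]
    warnings: pd.DataFrame
    days_induced: tuple[int, ...]


def default_tau(measurements: pd.DataFrame,
                day_uninduced: int = 3) -> dict[int, float]:
    """Per-plate detection threshold: 5% of the plate's median
    uninduced day-3 colony size (scanner-independent, robust to the
    small planted fraction of deficient strains)."""
    glu = measurements[(measurements["condition"] == CONDITION_UNINDUCED)
                       & (measurements["day"] == day_uninduced)]
    if glu.empty:
        raise ValueError("no uninduced measurements at the denominator day")
    med = glu.groupby("plate")["size"].median()
    return {int(p): TAU_MEDIAN_FRACTION * float(m) for p, m in med.items()}


def compute_growth_ratios(measurements: pd.DataFrame,
                          tau: float | dict[int, float] | None = None,
                          day_uninduced: int = 3,
                          days_induced: tuple[int, ...] = (3, 4, 5),
                          aggregate: str = "mean") -> ScoreResult:
    """Compute Gal/Glu ratios per replicate and aggregate per strain.

    Parameters
    ----------
    measurements
        Long table with columns plate,row,col,strain,condition,day,
        replicate,size (the dialect written by the simulator and the
        image quantifier).
    tau
        Detection threshold: scalar, per-plate mapping, or None for
        the 5%-of-plate-median default.
    aggregate
        "mean" (arithmetic, default) or "gmean" over finite replicate
        ratios.
    """
    if aggregate not in ("mean", "gmean"):
        raise ValueError("aggregate must be 'mean' or 'gmean'")
    required = {"plate", "strain", "condition", "day", "replicate", "size"}
    missing_cols = required - set(measurements.columns)
    if missing_cols:
        raise ValueError(f"measurements lack columns {sorted(missing_cols)}")

    if tau is None:
        tau_map = default_tau(measurements, day_uninduced)
    elif isinstance(tau, dict):
        tau_map = {int(k): float(v) for k, v in tau.items()}
    else:
        tau_map = {int(p): float(tau)
                   for p in measurements["plate"].unique()}

    glu = measurements[(measurements["condition"] == CONDITION_UNINDUCED)
                       & (measurements["day"] == day_uninduced)]
    gal = measurements[measurements["condition"] == CONDITION_INDUCED]

    u3 = glu.set_index(["strain", "replicate"])[["size", "plate"]]
    if u3.index.duplicated().any():
        raise ValueError("duplicate uninduced measurements per "
                         "(strain, replicate)")
    gal_piv = gal.pivot_table(index=["strain", "replicate"], columns="day",
                              values="size", aggfunc="first")

    rep_rows = []
    warn_rows = []
    strains = measurements["strain"].unique()
    u3_strains = set(u3.index.get_level_values(0))
    gal_strains = set(gal_piv.index.get_level_values(0))
    for strain in strains:
        has_u3 = strain in u3_strains
        if not has_u3 or strain not in gal_strains:
            warn_rows.append((strain, "missing_data",
                              "no uninduced denominator" if not has_u3
                              else "no induced measurements"))
            continue
        reps_u = u3.xs(strain, level=0)
        gal_strain = gal_piv.xs(strain, level=0)
        for rep, urow in reps_u.iterrows():
            plate = int(urow["plate"])
            t = tau_map.get(plate, 0.0)
            u = float(urow["size"])
            u_below = u < t
            row = {"strain": strain, "replicate": int(rep), "plate": plate,
                   "u3": u, "u3_below_tau": u_below}
            gal_rep = gal_strain.loc[rep] if rep in gal_strain.index else None
            for d in days_induced:
                i_d = (float(gal_rep[d]) if gal_rep is not None
                       and d in gal_rep.index and pd.notna(gal_rep[d])
                       else np.nan)
                below = bool(i_d < t) if np.isfinite(i_d) else False
                if not np.isfinite(i_d):
                    r = np.nan
                elif u_below:
                    r = np.nan  # unevaluable: denominator unmeasurable
                else:
                    r = 0.0 if below else i_d / u
                row[f"r{d}"] = r
                row[f"i{d}_below_tau"] = below
            rep_rows.append(row)

    replicates = pd.DataFrame(rep_rows)
    warnings_df = pd.DataFrame(warn_rows,
                               columns=["strain", "reason", "detail"])
    if replicates.empty:
        strains_df = pd.DataFrame(columns=["strain"])
        return ScoreResult(replicates, strains_df, tau_map, warnings_df,
                           tuple(days_induced))

    def _agg(values: pd.Series) -> float:
        finite = values[np.isfinite(values)]
        if finite.empty:
            return np.nan
        if aggregate == "mean":
            return float(finite.mean())
        if (finite == 0).any():
            return 0.0
        return float(np.exp(np.log(finite).mean()))

    grouped = replicates.groupby("strain", sort=True)
    records = []
    for strain, grp in grouped:
        rec = {"strain": strain,
               "plate": int(grp["plate"].iloc[0]),
               "n_replicates": int(len(grp)),
               "glu_deficient_observed": bool(grp["u3_below_tau"].all())}
        for d in days_induced:
            rec[f"r{d}"] = _agg(grp[f"r{d}"])
            # zero only if induced below τ in ALL replicates at that day
            rec[f"zero_d{d}"] = bool(grp[f"i{d}_below_tau"].all())
        records.append(rec)
    strains_df = pd.DataFrame(records)
    if not warnings_df.empty:
        warnings.warn(f"{len(warnings_df)} strain(s) excluded from scoring "
                      "for missing measurements", stacklevel=2)
    return ScoreResult(replicates, strains_df, tau_map, warnings_df,
                       tuple(days_induced))
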