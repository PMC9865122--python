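"""Hit calling: enhancer / protective gene classification.

Terminology is fixed at the gene level: an ``enhancer_gene`` is a gene
whose deletion rescues growth under Aβ induction (aggregate day-4
Gal/Glu ratio >= 0.7, inclusive) — the gene contributes to toxicity.
A ``protective_gene`` is a gene whose deletion abolishes growth under
induction (day-5 ratio 0 under the all-replicate below-threshold rule)
— the gene normally protects.  Confounders are excluded first: strains
on the known galactose-deficiency list and strains with observed
deficient growth on glucose (uninduced day-3 size below τ in every
replicate).

The volcano statistic is an annotation, not a gate: per-strain
log2 fold change of the day-4 ratio against the plate's Aβ control
pool, with a plate-robust z score (1.4826·MAD scale) and BH q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .score import ScoreResult

__all__ = ["HitThresholds", "apply_confounder_filters", "call_hits",
           "volcano_statistics", "run_hit_calling"]

LOG2FC_EPSILON = 1e-3  # pseudo-ratio admitting zero ratios into log2FC

CALL_ENHANCER = "enhancer_gene"
CALL_PROTECTIVE = "protective_gene"
CALL_NONE = "no_call"
CALL_EXCLUDED = "excluded"


@dataclass(frozen=True)
class HitThresholds:
    """Classification thresholds.

    ``rescue_threshold`` (0.7, inclusive) applies to the aggregate
    ratio at ``rescue_day`` (4); the zero rule applies at ``zero_day``
    (5).  ``fdr_level`` annotates volcano significance.
    """

    rescue_threshold: float = 0.7
    rescue_day: int = 4
    zero_day: int = 5
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.rescue_threshold <= 0:
            raise ValueError("rescue_threshold must be positive")
        if self.rescue_day == self.zero_day:
            raise ValueError("rescue_day and zero_day must differ")
        for d in (self.rescue_day, self.zero_day):
            if d not in (3, 4, 5):
                raise ValueError("days must be in {3, 4, 5}")


def apply_confounder_filters(strains: pd.DataFrame,
                             known_gal_deficient: list[str] = (),
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard galactose- and glucose-deficiency confounders.

    Returns (retained strain table, exclusions table with columns
    strain, reason) where reason is ``gal_deficient_known`` or
    ``glu_deficient_observed``.  A strain can carry both reasons.
    """
    gal_set = set(known_gal_deficient)
    excl_rows = []
    drop = pd.Series(False, index=strains.index)
    for idx, rec in strains.iterrows():
        if rec["strain"] in gal_set:
            excl_rows.append((rec["strain"], "gal_deficient_known"))
            drop[idx] = True
        if bool(rec.get("glu_deficient_observed", False)):
            excl_rows.append((rec["strain"], "glu_deficient_observed"))
            drop[idx] = True
    retained = strains[~drop].reset_index(drop=True)
    exclusions = pd.DataFrame(excl_rows, columns=["strain", "reason"])
    return retained, exclusions


def call_hits(strains: pd.DataFrame,
              thresholds: HitThresholds = HitThresholds()) -> pd.DataFrame:
    """Apply the threshold rules to confounder-filtered strain scores.

    Returns columns strain, call, r{rescue_day}, r{zero_day}.  The
    rescue rule (inclusive >=) takes precedence; with a positive
    threshold the two rules cannot both describe the same biology, and
    any strain matching neither is ``no_call``.
    """
    r_col = f"r{thresholds.rescue_day}"
    z_col = f"zero_d{thresholds.zero_day}"
    rz_col = f"r{thresholds.zero_day}"
    for col in (r_col, z_col):
        if col not in strains.columns:
            raise ValueError(f"strain table lacks column {col!r}")
    calls = []
    for _, rec in strains.iterrows():
        r4 = rec[r_col]
        if np.isfinite(r4) and r4 >= thresholds.rescue_threshold:
            call = CALL_ENHANCER
        elif bool(rec[z_col]):
            call = CALL_PROTECTIVE
        else:
            call = CALL_NONE
        calls.append((rec["strain"], call, r4, rec.get(rz_col, np.nan)))
    return pd.DataFrame(calls, columns=["strain", "call", r_col, rz_col])


def volcano_statistics(strains: pd.DataFrame,
                       control_strains: list[str],
                       day: int = 4,
                       epsilon: float = LOG2FC_EPSILON) -> pd.DataFrame:
    """Per-strain (log2FC, p, q) of the day-4 ratio vs the control pool.

    log2FC = log2((r + eps) / (r_control + eps)).  The z score uses a
    per-plate robust scale s = 1.4826 * MAD of all strain aggregate
    ratios on the plate (falling back to the plate SD when MAD is 0);
    p is two-sided normal, q is BH over all tested strains.  The
    statistic is a stand-in: the screen's own volcano analysis is not
    specified, so outputs carry a ``statistic`` tag.
    """
    r_col = f"r{day}"
    ctrl = strains[strains["strain"].isin(set(control_strains))]
    if ctrl.empty:
        raise ValueError("no control strains present in the score table")
    ctrl_mean = float(ctrl[r_col].mean())

    tested = strains[~strains["strain"].isin(set(control_strains))].copy()
    tested = tested[np.isfinite(tested[r_col])]
    if tested.empty:
        return pd.DataFrame(columns=["strain", "log2fc", "z", "p", "q",
                                     "flag"])

    scale_by_plate: dict[int, float] = {}
    for plate, grp in strains.groupby("plate"):
        vals = grp[r_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        mad = float(np.median(np.abs(vals - np.median(vals)))) if vals.size else 0.0
        s = 1.4826 * mad
        if s == 0.0:
            s = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        scale_by_plate[int(plate)] = s

    rows = []
    for _, rec in tested.iterrows():
        r = float(rec[r_col])
        log2fc = np.log2((r + epsilon) / (ctrl_mean + epsilon))
        s = scale_by_plate.get(int(rec["plate"]), 0.0)
        if s > 0:
            z = (r - ctrl_mean) / s
            p = 2.0 * stats.norm.sf(abs(z))
            flag = ""
        else:
            z, p, flag = np.nan, np.nan, "scale_undefined"
        rows.append((rec["strain"], log2fc, z, p, flag))
    out = pd.DataFrame(rows, columns=["strain", "log2fc", "z", "p", "flag"])
    q = np.full(len(out), np.nan)
    ok = np.isfinite(out["p"].to_numpy(dtype=float))
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["q"] = q
    out.attrs["statistic"] = ("plate-robust z (1.4826*MAD) vs Abeta control "
                              "pool; stand-in, not the screen's original "
                              "volcano test")
    return out[["strain", "log2fc", "z", "p", "q", "flag"]]


def run_hit_calling(scores: ScoreResult,
                    known_gal_deficient: list[str] = (),
                    thresholds: HitThresholds = HitThresholds(),
                    control_strains: list[str] = ()) -> pd.DataFrame:
    """Full classification: filters, threshold calls, volcano annotation.

    Every strain that entered scoring receives exactly one call in
    {enhancer_gene, protective_gene, no_call, excluded}; excluded rows
    carry comma-joined reason codes (gal_deficient_known,
    glu_deficient_observed, missing_data, control).  Control strains
    are reported as excluded/control so library partitions stay clean.
    """
    strains = scores.strains
    retained, exclusions = apply_confounder_filters(
        strains, known_gal_deficient)

    ctrl_set = set(control_strains)
    ctrl_mask = retained["strain"].isin(ctrl_set)
    library = retained[~ctrl_mask].reset_index(drop=True)

    called = call_hits(library, thresholds)

    volcano = None
    if ctrl_set and strains["strain"].isin(ctrl_set).any():
        volcano = volcano_statistics(retained, sorted(ctrl_set),
                                     day=thresholds.rescue_day)

    reason_map: dict[str, list[str]] = {}
    for _, rec in exclusions.iterrows():
        reason_map.setdefault(rec["strain"], []).append(rec["reason"])
    for _, rec in scores.warnings.iterrows():
        reason_map.setdefault(rec["strain"], []).append(rec["reason"])
    for sid in sorted(ctrl_set & set(retained["strain"])):
        reason_map.setdefault(sid, []).append("control")

    rows = []
    r_col = f"r{thresholds.rescue_day}"
    rz_col = f"r{thresholds.zero_day}"
    by_strain = strains.set_index("strain")
    for _, rec in called.iterrows():
        rows.append((rec["strain"], rec["call"], "",
                     rec[r_col], rec[rz_col]))
    for sid, reasons in reason_map.items():
        r4 = by_strain[r_col].get(sid, np.nan) if r_col in by_strain else np.nan
        r5 = by_strain[rz_col].get(sid, np.nan) if rz_col in by_strain else np.nan
        rows.append((sid, CALL_EXCLUDED, ",".join(sorted(set(reasons))),
                     r4, r5))
    out = pd.DataFrame(rows, columns=["strain", "call", "reasons",
                                      r_col, rz_col])
    if volcano is not None:
        out = out.merge(volcano[["strain", "log2fc", "z", "p", "q"]],
                        on="strain", how="left")
        out.attrs["volcano_statistic"] = volcano.attrs.get("statistic", "")
    return out.sort_values("strain", kind="mergesort").reset_index(drop=True)
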