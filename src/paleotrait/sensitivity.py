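"""Trait-database error-injection simulation.

Trait compilations inherit misidentifications and transcription errors
(estimated around 10% of species for mycorrhizal assignments). Robustness
is assessed by randomly reassigning trait categories for a fraction of
MOTUs — in mycorrhizal status, mycorrhizal type (except ERM) and
pollination mode; ERM assignments and N-fixation are treated as
phylogenetically conserved and therefore reliable — then recomputing the
per-sample trait composition and the most conservative trait-niche model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import sample_trait_shares
from .io_core import TRAIT_LEVELS, ValidationError, check_nm_consistency
from .omi import omi_analysis, trait_niche_models

__all__ = ["SensitivityConfig", "SUSCEPTIBLE_TRAITS", "perturb_traits",
           "sensitivity_curve", "sensitivity_model_rerun"]

#: Traits exposed to random error.
SUSCEPTIBLE_TRAITS = ("myc_status", "myc_type", "pollination")


@dataclass
class SensitivityConfig:
    error_rates: tuple = (0.01, 0.05, 0.10, 0.20)
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if any(not 0 < r < 1 for r in self.error_rates):
            raise ValidationError("error rates must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


def perturb_traits(tt: pd.DataFrame, rate: float, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   return_audit: bool = False):
    """Randomly reassign trait categories at a given error rate.

    For each susceptible trait independently, ``round(rate * S)`` MOTUs
    (S = table size) are drawn uniformly without replacement from the
    eligible pool and given a uniform draw from the other permitted
    categories. ERM MOTUs are ineligible for type perturbation and ERM is
    never a reassignment target; N-fixation is never touched. The NM
    type <=> status invariant survives through a coupling rule: a type
    moving to/from NM drags status with it (to NM, or to a uniform OM/FM
    draw), a status moving to NM forces type to NM (so ERM-typed MOTUs may
    not receive NM status), and a status leaving NM sends type to a
    uniform AM/ECM draw.
    """
    if not 0 < rate < 1:
        raise ValidationError("rate must lie in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = tt.copy()
    S = len(out)
    k = int(round(rate * S))
    if k == 0:
        import warnings

        warnings.warn(f"rate {rate} selects 0 of {S} MOTUs; returning the table unchanged")
        return (out, {t: np.array([], dtype=int) for t in SUSCEPTIBLE_TRAITS}) if return_audit else out

    audit: dict[str, np.ndarray] = {}

    def reassign(trait: str, eligible: np.ndarray, choices_of) -> np.ndarray:
        pool = np.flatnonzero(eligible)
        sel = rng.choice(pool, size=min(k, len(pool)), replace=False)
        for i in sel:
            opts = choices_of(i)
            out.iloc[i, out.columns.get_loc(trait)] = opts[rng.integers(len(opts))]
        audit[trait] = sel
        return sel

    # mycorrhizal type: ERM rows protected, ERM never a target
    type_col = out["myc_type"].to_numpy()
    sel = reassign(
        "myc_type",
        type_col != "ERM",
        lambda i: [c for c in ("AM", "ECM", "NM") if c != type_col[i]],
    )
    for i in sel:
        new_t = out.iloc[i, out.columns.get_loc("myc_type")]
        st_loc = out.columns.get_loc("myc_status")
        if new_t == "NM":
            out.iloc[i, st_loc] = "NM"
        elif out.iloc[i, st_loc] == "NM":
            out.iloc[i, st_loc] = ("OM", "FM")[rng.integers(2)]

    # mycorrhizal status: NM not offered to ERM-typed MOTUs
    status_col = out["myc_status"].to_numpy()
    type_now = out["myc_type"].to_numpy()
    sel = reassign(
        "myc_status",
        np.ones(S, dtype=bool),
        lambda i: [c for c in ("OM", "FM", "NM")
                   if c != status_col[i] and not (c == "NM" and type_now[i] == "ERM")],
    )
    for i in sel:
        new_s = out.iloc[i, out.columns.get_loc("myc_status")]
        ty_loc = out.columns.get_loc("myc_type")
        if new_s == "NM":
            out.iloc[i, ty_loc] = "NM"
        elif out.iloc[i, ty_loc] == "NM":
            out.iloc[i, ty_loc] = ("AM", "ECM")[rng.integers(2)]

    poll_col = out["pollination"].to_numpy()
    reassign(
        "pollination",
        np.ones(S, dtype=bool),
        lambda i: [c for c in ("insect", "wind") if c != poll_col[i]],
    )
    check_nm_consistency(out)
    return (out, audit) if return_audit else out


def _flat_shares(rm: pd.DataFrame, tt: pd.DataFrame) -> np.ndarray:
    """Flattened per-sample read-weighted shares over the susceptible traits."""
    parts = [sample_trait_shares(rm, tt, t, "reads").to_numpy().ravel()
             for t in SUSCEPTIBLE_TRAITS]
    return np.concatenate(parts)


def sensitivity_curve(
    rm: pd.DataFrame,
    tt: pd.DataFrame,
    cfg: SensitivityConfig | None = None,
) -> pd.DataFrame:
    """Correlation between original and perturbed trait composition, per rate.

    For each rate and replicate: perturb the trait table, recompute the
    per-sample read-weighted shares of the susceptible traits, and Pearson-
    correlate the flattened share vector against the original. Returns a
    long table (rate, rep, correlation); replicates whose perturbed share
    vector is constant are flagged with NaN.
    """
    cfg = cfg or SensitivityConfig()
    rng = np.random.default_rng(cfg.seed)
    base = _flat_shares(rm, tt)
    base_c = base - base.mean()
    rows = []
    for rate in cfg.error_rates:
        for rep in range(cfg.n_reps):
            pert = perturb_traits(tt, rate, rng=rng)
            v = _flat_shares(rm, pert)
            vc = v - v.mean()
            denom = np.sqrt((base_c**2).sum() * (vc**2).sum())
            r = float(base_c @ vc / denom) if denom > 0 else np.nan
            rows.append({"rate": rate, "rep": rep, "correlation": r})
    return pd.DataFrame(rows)


def sensitivity_model_rerun(
    rm: pd.DataFrame,
    tt: pd.DataFrame,
    periods: pd.Series,
    rate: float = 0.10,
    n_reps: int = 100,
    n_perm: int = 199,
    seed: int = 0,
    focal: str = "myc_status",
) -> dict:
    """Median R2 and p of the conservative trait-niche model under error.

    Per replicate the trait table is perturbed at ``rate``, the OMI
    ordination recomputed scores are reused (traits do not enter the
    ordination), and the focal term of model (iii) — focal trait after
    growth form and non-confounded mutualist traits — is re-estimated.
    Replicates where the model fails are dropped and counted.
    """
    res = omi_analysis(rm, periods)
    scores = res.species_scores.iloc[:, :2]
    rng = np.random.default_rng(seed)

    def focal_stats(table: pd.DataFrame) -> tuple[float, float]:
        models = trait_niche_models(scores, table, n_perm=n_perm,
                                    seed=int(rng.integers(2**31)))
        term = models[focal]["after_growth_form_and_traits"].term(focal)
        return float(term["R2"]), float(term["p"])

    r2_orig, p_orig = focal_stats(tt)
    r2s, ps, failures = [], [], 0
    for _ in range(n_reps):
        try:
            pert = perturb_traits(tt, rate, rng=rng)
            r2, p = focal_stats(pert)
            r2s.append(r2)
            ps.append(p)
        except Exception:
            failures += 1
    return {
        "original_R2": r2_orig, "original_p": p_orig,
        "median_R2": float(np.median(r2s)) if r2s else np.nan,
        "median_p": float(np.median(ps)) if ps else np.nan,
        "n_reps": len(r2s), "failures": failures, "rate": rate,
    }
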