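"""Posterior summarisation and disturbance-effect classification.

Per species x regime, the dispersal parameter reported is the posterior mean
and 95% credible interval (2.5th/97.5th linear-interpolation percentiles) of
the kernel's mean dispersal distance, obtained by mapping each retained
``u`` draw through ``(pi/2) sqrt(u)``.  A species counts as affected by
disturbance when a disturbed regime's CI fails to intersect the protected
CI (closed intervals, compared at the precision supplied).  Group-level
summaries average the per-cell means by dispersal vector or by regime.

Packaged with the module are printed-table transcriptions of per-species
dispersal and covariate-effect estimates for 33 Afrotropical tree species
under protected, logged and hunted+logged forest, used as fixtures for this
stage of the pipeline.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError, ReferentialError
from .kernel import mean_distance
from .mcmc import PosteriorSamples

__all__ = [
    "summarize_posterior",
    "classify_overlap",
    "count_affected",
    "group_mean_dispersal",
    "effect_sign_table",
    "load_printed_table1",
    "load_printed_table2",
]

DISTURBED_REGIMES = ("logged", "hunted_logged")
_COVARIATE_FOR_BETA = {"diameter": "diameter", "logging": "logging",
                       "hunting_logging": "hunting_logging"}
_BETA_FOR_COVARIATE = {"diameter": "diameter", "logging": "logging",
                       "hunting_logging": "hunting_logging"}


def _ci(draws):
    lo, hi = np.percentile(draws, [2.5, 97.5])  # linear interpolation
    return float(np.mean(draws)), float(lo), float(hi)


def summarize_posterior(samples: PosteriorSamples):
    """(dispersal table, effect table) from one species' retained draws.

    Dispersal rows: species, regime, mean_m, ci_lo_m, ci_hi_m — summaries of
    mean dispersal distance draws.  Effect rows: species, covariate,
    posterior_mean, ci_lo, ci_hi on the log-fecundity (beta) scale.
    """
    if samples.n_draws < 100:
        raise ValidationError("need at least 100 retained draws to summarise")
    disp_rows = []
    for g, regime in enumerate(samples.regimes):
        m, lo, hi = _ci(mean_distance(samples.u[:, g]))
        disp_rows.append((samples.species, regime, m, lo, hi))
    dispersal = pd.DataFrame(
        disp_rows, columns=["species", "regime", "mean_m", "ci_lo_m", "ci_hi_m"])
    eff_rows = []
    for covariate in ("diameter", "logging", "hunting_logging"):
        j = samples.beta_names.index(covariate)
        m, lo, hi = _ci(samples.beta[:, j])
        eff_rows.append((samples.species, covariate, m, lo, hi))
    effects = pd.DataFrame(
        eff_rows, columns=["species", "covariate", "posterior_mean", "ci_lo", "ci_hi"])
    return dispersal, effects


def _check_interval(row):
    if not (row["ci_lo_m"] <= row["mean_m"] <= row["ci_hi_m"]):
        raise ValidationError(
            f"malformed interval for {row['species']} {row['regime']}: "
            f"[{row['ci_lo_m']}, {row['ci_hi_m']}] around {row['mean_m']}")


def intervals_overlap(lo_a, hi_a, lo_b, hi_b) -> bool:
    """Closed-interval overlap at the supplied precision."""
    return max(lo_a, lo_b) <= min(hi_a, hi_b)


def classify_overlap(row_protected, row_logged, row_hunted_logged) -> dict:
    """CI-overlap classification of one species' disturbance response.

    Each row is a mapping with species, regime, mean_m, ci_lo_m, ci_hi_m.
    A disturbed regime whose CI does not intersect the protected CI gets
    direction 'higher' or 'lower' by its mean; 'none' otherwise.
    """
    rows = {r["regime"]: r for r in
            (dict(row_protected), dict(row_logged), dict(row_hunted_logged))}
    if set(rows) != {"protected", *DISTURBED_REGIMES}:
        raise ValidationError(f"expected one row per regime, got {sorted(rows)}")
    species = {r["species"] for r in rows.values()}
    if len(species) != 1:
        raise ValidationError(f"rows mix species {sorted(species)}")
    for r in rows.values():
        _check_interval(r)
    prot = rows["protected"]
    direction = {}
    for regime in DISTURBED_REGIMES:
        d = rows[regime]
        if intervals_overlap(prot["ci_lo_m"], prot["ci_hi_m"],
                             d["ci_lo_m"], d["ci_hi_m"]):
            direction[regime] = "none"
        else:
            direction[regime] = "higher" if d["mean_m"] > prot["mean_m"] else "lower"
    return {"species": species.pop(),
            "affected": any(v != "none" for v in direction.values()),
            "direction": direction}


def classify_table(dispersal: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`classify_overlap` to every species of a long-format table."""
    rows = []
    for sp, g in dispersal.groupby("species", sort=True):
        byreg = {r["regime"]: r for _, r in g.iterrows()}
        c = classify_overlap(byreg["protected"], byreg["logged"], byreg["hunted_logged"])
        rows.append((sp, c["affected"], c["direction"]["logged"],
                     c["direction"]["hunted_logged"]))
    return pd.DataFrame(rows, columns=["species", "affected", "logged", "hunted_logged"])


def count_affected(classifications: pd.DataFrame, traits: pd.DataFrame) -> dict:
    """Totals of CI-nonoverlap species overall and per dispersal vector."""
    if len(classifications) == 0:
        return {"total": (0, 0)}
    missing = sorted(set(classifications["species"]) - set(traits["species"]))
    if missing:
        raise ReferentialError(f"species without trait records: {missing}")
    merged = classifications.merge(traits[["species", "vector"]], on="species")
    out = {"total": (int(merged["affected"].sum()), len(merged))}
    for vec, g in merged.groupby("vector"):
        out[vec] = (int(g["affected"].sum()), len(g))
    return out


def group_mean_dispersal(estimates: pd.DataFrame, by: str,
                         traits: pd.DataFrame | None = None) -> pd.Series:
    """Arithmetic mean of mean_m over each group's species x regime cells.

    ``by`` is 'vector' (requires traits unless the table carries a vector
    column) or 'regime'.  Values are reported to 0.1 m.
    """
    df = estimates
    if by == "vector" and "vector" not in df.columns:
        if traits is None:
            raise ReferentialError("grouping by vector needs a trait table")
        df = df.merge(traits[["species", "vector"]], on="species")
    if by not in df.columns:
        raise ValidationError(f"cannot group by {by!r}")
    groups = df.groupby(by)["mean_m"].mean().round(1)
    if (df.groupby(by).size() == 0).any() or groups.empty:
        raise ValidationError("undefined (empty) group")
    return groups


def effect_sign_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate sign of each species' effect CI: positive if the whole
    CI is above zero, negative if below, else null (at supplied precision)."""
    sign = np.where(effects["ci_lo"] > 0, "positive",
                    np.where(effects["ci_hi"] < 0, "negative", "null"))
    out = effects[["species", "covariate"]].copy()
    out["sign"] = sign
    return out


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("seedshadow.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_printed_table1() -> pd.DataFrame:
    """Transcribed per-species dispersal estimates (m) with 95% CIs, long
    format: species, vector, regime, mean_m, ci_lo_m, ci_hi_m (33 x 3 rows)."""
    return _load_packaged("table1_dispersal.csv")


def load_printed_table2() -> pd.DataFrame:
    """Transcribed covariate effects on conditional fecundity: species,
    vector, covariate, posterior_mean, ci_lo, ci_hi (33 x 3 rows)."""
    return _load_packaged("table2_effects.csv")
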