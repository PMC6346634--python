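"""Read, validate and write the tabular formats connecting censuses, traps,
counts, traits and configuration.

All tables are plain comma-separated UTF-8 with a header row and '.' decimals.
Coordinates are metres from the plot's south-west corner; plots are
axis-aligned squares (100 m side by default).  Collections are returned as
pandas DataFrames with one validated row per record.

Schemas
-------
``trees.csv``       plot_id,tree_id,species,x_m,y_m,dbh_cm,regime
``traps.csv``       plot_id,trap_id,x_m,y_m,area_m2,season_fraction
``seed_counts.csv`` plot_id,trap_id,species,year,count
``traits.csv``      species,vector
``config.yaml``     keys mirroring :class:`AnalysisConfig`
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ReferentialError, ValidationError

REGIMES = ("protected", "logged", "hunted_logged")
VECTORS = ("animal", "abiotic", "both")
DBH_CENSUS_MIN_CM = 10.0
#: minimum trap distance from any plot border used by the design (m)
TRAP_BORDER_MARGIN_M = 20.0

TREE_COLUMNS = ["plot_id", "tree_id", "species", "x_m", "y_m", "dbh_cm", "regime"]
TRAP_COLUMNS = ["plot_id", "trap_id", "x_m", "y_m", "area_m2", "season_fraction"]
COUNT_COLUMNS = ["plot_id", "trap_id", "species", "year", "count"]
TRAIT_COLUMNS = ["species", "vector"]


@dataclass
class AnalysisConfig:
    """Plot geometry, MCMC settings, prior bounds and maturation parameters."""

    plot_side_m: float = 100.0
    n_iter: int = 50_000
    burn_in: int = 1_000
    thin: int = 10
    rng_seed: int = 0
    proposal_scale_log_psi: float = 0.5
    proposal_scale_log_u: float = 0.15
    u_min: float = 0.4052847345693511   # mean distance 1 m
    u_max: float = 9118.906527810399    # mean distance 150 m
    ig_shape: float = 2.0               # fixed degrees of freedom of variance priors
    ig_scale: float = 0.25
    maturation_mu_log_cm: float = 2.995732273553991   # log(20 cm)
    maturation_sigma_log: float = 0.5
    output_dir: str = "results"

    def __post_init__(self):
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValidationError(
                f"need iterations > burn_in >= 0, got {self.n_iter}, {self.burn_in}"
            )


def read_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = AnalysisConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def write_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def _read_csv(path, columns, kind: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (FileNotFoundError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read {kind} table at {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{kind} table {path} lacks required column(s) {missing}")
    return df[columns].copy()


def read_tree_census(path, plot_side_m: float = 100.0) -> pd.DataFrame:
    """Load a tree census, enforcing the >=10 cm DBH cut-off and plot bounds."""
    df = _read_csv(path, TREE_COLUMNS, "tree census")
    bad = df.index[df["dbh_cm"] < DBH_CENSUS_MIN_CM].tolist()
    if bad:
        raise ValidationError(
            f"dbh_cm below the {DBH_CENSUS_MIN_CM} cm census threshold in rows {bad}"
        )
    _check_coords(df, plot_side_m, "tree census")
    badreg = sorted(set(df["regime"]) - set(REGIMES))
    if badreg:
        raise ValidationError(f"unknown regime label(s) {badreg}; expected {REGIMES}")
    nreg = df.groupby("plot_id")["regime"].nunique()
    mixed = nreg.index[nreg > 1].tolist()
    if mixed:
        raise ValidationError(f"regime is not constant within plot(s) {mixed}")
    return df


def read_traps(path, plot_side_m: float = 100.0) -> pd.DataFrame:
    df = _read_csv(path, TRAP_COLUMNS, "trap")
    if (df["area_m2"] <= 0).any():
        raise ValidationError("trap area_m2 must be positive")
    sf = df["season_fraction"]
    if ((sf <= 0) | (sf > 1)).any():
        raise ValidationError("season_fraction must lie in (0, 1]")
    _check_coords(df, plot_side_m, "trap")
    return df


def read_seed_counts(path, traps: pd.DataFrame) -> pd.DataFrame:
    """Load seed counts; effort A (m^2 yr) is computed from the trap table."""
    df = _read_csv(path, COUNT_COLUMNS, "seed count")
    if (df["count"] < 0).any():
        raise ValidationError("seed counts must be non-negative")
    if df["count"].dtype.kind not in "iu":
        if not np.allclose(df["count"], np.round(df["count"])):
            raise ValidationError("seed counts must be integers")
        df["count"] = df["count"].astype(int)
    known = set(zip(traps["plot_id"], traps["trap_id"]))
    referenced = set(zip(df["plot_id"], df["trap_id"]))
    orphans = sorted(referenced - known)
    if orphans:
        raise ReferentialError(f"seed counts reference unknown trap(s) {orphans}")
    dup = df.duplicated(subset=["plot_id", "trap_id", "species", "year"])
    if dup.any():
        raise ValidationError(
            f"duplicate (trap, species, year) rows at index {df.index[dup].tolist()}"
        )
    effort = traps.set_index(["plot_id", "trap_id"])
    effort = (effort["area_m2"] * effort["season_fraction"]).rename("effort_A")
    out = df.join(effort, on=["plot_id", "trap_id"])
    return out


def read_traits(path) -> pd.DataFrame:
    df = _read_csv(path, TRAIT_COLUMNS, "trait")
    badvec = sorted(set(df["vector"]) - set(VECTORS))
    if badvec:
        raise ValidationError(f"unknown dispersal vector(s) {badvec}; expected {VECTORS}")
    if df["species"].duplicated().any():
        raise ValidationError("duplicate species in trait table")
    return df


def _check_coords(df, plot_side_m, kind):
    oob = df.index[
        (df["x_m"] < 0) | (df["x_m"] > plot_side_m)
        | (df["y_m"] < 0) | (df["y_m"] > plot_side_m)
    ].tolist()
    if oob:
        raise ValidationError(f"{kind} coordinates outside [0, {plot_side_m}] m in rows {oob}")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any record collection; inverse of the readers (field-for-field)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Structured cross-reference report; warnings never raise."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def empty(self) -> bool:
        return not self.errors and not self.warnings


def validate_dataset(trees, traps, counts, traits, plot_side_m: float = 100.0) -> ValidationReport:
    """Cross-check a full dataset.  Pure: inputs are not mutated.

    Errors: broken cross-references (species/traps/plots).  Warnings: species
    with zero total seeds (fecundity unidentifiable) and traps closer than
    20 m to a plot border (the field design keeps traps >=20 m inside).
    """
    rep = ValidationReport()
    trap_keys = set(zip(traps["plot_id"], traps["trap_id"]))
    for key in sorted(set(zip(counts["plot_id"], counts["trap_id"])) - trap_keys):
        rep.errors.append(f"count references unknown trap {key}")
    tree_plots = set(trees["plot_id"])
    for p in sorted(set(traps["plot_id"]) - tree_plots):
        rep.errors.append(f"traps in plot {p!r} but no censused trees there")
    trait_species = set(traits["species"])
    for sp in sorted(set(counts["species"]) - trait_species):
        rep.errors.append(f"species {sp!r} in counts has no trait record")
    totals = counts.groupby("species")["count"].sum()
    for sp in sorted(totals.index[totals == 0]):
        rep.warnings.append(f"species {sp!r} has zero total seeds; fecundity unidentifiable")
    margin = TRAP_BORDER_MARGIN_M
    for row in traps.itertuples():
        border = min(row.x_m, row.y_m, plot_side_m - row.x_m, plot_side_m - row.y_m)
        if border < margin:
            rep.warnings.append(
                f"trap {row.trap_id!r} in plot {row.plot_id!r} is {border:g} m from a "
                f"border (design minimum {margin:g} m)"
            )
    return rep
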