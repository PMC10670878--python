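"""Cell-specific SILAC analysis of heavy-arginine incorporation.

Peptides from an MS search export are classified by the sigma-factor
regulon(s) of their source protein: SigF/SigG regulons are transcribed in
the forespore, SigE/SigK in the mother cell, and membership in the SigA,
SigH or Spo0A regulons marks vegetative expression and takes precedence
(such proteins are present before the asymmetric division, so their
labeling says nothing about compartment-specific import). Arginine-
containing, compartment-specific peptides are then summarized as the
fraction carrying at least one heavy (13C6,15N4) arginine, with Wilson 95%
intervals and fold-changes over a control scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

VEGETATIVE_REGULONS = frozenset({"SigA", "SigH", "Spo0A"})
FORESPORE_REGULONS = frozenset({"SigF", "SigG"})
MOTHER_CELL_REGULONS = frozenset({"SigE", "SigK"})
KNOWN_REGULONS = VEGETATIVE_REGULONS | FORESPORE_REGULONS | MOTHER_CELL_REGULONS

#: canonical column name -> accepted aliases in input tables
DEFAULT_ALIASES = {
    "peptide_id": ("peptide_id", "peptide", "pep_id"),
    "protein_id": ("protein_id", "protein", "accession"),
    "arg_count": ("arg_count", "num_arg", "n_arg", "r_count"),
    "heavy": ("heavy", "is_heavy", "heavy_label"),
}


@dataclass
class PeptideRecord:
    """One peptide-level MS record."""

    peptide_id: str
    protein_id: str
    arg_count: int
    heavy: bool
    sequence: str | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.heavy and self.arg_count < 1:
            raise ValueError("a heavy peptide must contain at least one arginine")


@dataclass
class CompartmentAssignment:
    """Deterministic compartment call for one protein."""

    compartment: str  # mother_cell | forespore | vegetative | ambiguous | unknown
    regulons: frozenset = field(default_factory=frozenset)


@dataclass
class FilterReport:
    """Where every input peptide landed; counts sum to the input size."""

    n_input: int
    n_no_arginine: int
    n_vegetative: int
    n_ambiguous: int
    n_unknown: int
    n_mother_cell: int
    n_forespore: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class IncorporationSummary:
    """Heavy-arginine incorporation fractions with Wilson 95% intervals.

    ``table`` has one row per group with columns ``group_type``
    ("compartment" or "regulon"), ``group``, ``n_peptides``, ``n_heavy``,
    ``fraction``, ``ci_low``, ``ci_high``.
    """

    table: pd.DataFrame

    def fraction(self, group: str) -> float:
        row = self.table[self.table["group"] == group]
        if row.empty:
            raise KeyError(f"no group {group!r} in summary")
        return float(row["fraction"].iloc[0])

    def interval(self, group: str) -> tuple[float, float]:
        row = self.table[self.table["group"] == group]
        if row.empty:
            raise KeyError(f"no group {group!r} in summary")
        return float(row["ci_low"].iloc[0]), float(row["ci_high"].iloc[0])


def load_regulon_map(source: str | Path | pd.DataFrame) -> dict[str, frozenset]:
    """Load a protein -> regulon-set map from a TSV or DataFrame.

    Expected columns: ``protein_id`` and ``regulons`` (comma-separated for
    multi-membership). Each protein may appear only once.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(Path(source), sep="\t")
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"proteins listed more than once in regulon map: {dupes}")
    mapping = {}
    for _, row in df.iterrows():
        regs = frozenset(
            r.strip() for r in str(row["regulons"]).split(",") if r.strip()
        )
        unknown = regs - KNOWN_REGULONS
        if unknown:
            raise ValueError(
                f"unknown regulon names {sorted(unknown)} for {row['protein_id']}"
            )
        mapping[str(row["protein_id"])] = regs
    return mapping


def assign_compartment(
    protein_id: str, regulon_map: dict[str, frozenset]
) -> CompartmentAssignment:
    """Compartment of a protein from its regulon memberships.

    Vegetative membership (SigA/SigH/Spo0A) takes precedence; otherwise
    SigF/SigG imply forespore and SigE/SigK mother cell; both cell types
    without vegetative membership is ambiguous; no known regulon (or a
    protein absent from the map) is unknown.
    """
    regs = regulon_map.get(protein_id)
    if regs is None:
        return CompartmentAssignment("unknown")
    if regs & VEGETATIVE_REGULONS:
        return CompartmentAssignment("vegetative", regs)
    is_fs = bool(regs & FORESPORE_REGULONS)
    is_mc = bool(regs & MOTHER_CELL_REGULONS)
    if is_fs and is_mc:
        return CompartmentAssignment("ambiguous", regs)
    if is_fs:
        return CompartmentAssignment("forespore", regs)
    if is_mc:
        return CompartmentAssignment("mother_cell", regs)
    return CompartmentAssignment("unknown", regs)


def _canonicalize(table: pd.DataFrame, aliases: dict | None) -> pd.DataFrame:
    lookup = dict(DEFAULT_ALIASES)
    if aliases:
        lookup.update({k: tuple(v) for k, v in aliases.items()})
    renames = {}
    for canonical, options in lookup.items():
        if canonical in table.columns:
            continue
        for opt in options:
            if opt in table.columns:
                renames[opt] = canonical
                break
    table = table.rename(columns=renames)
    missing = {"protein_id", "arg_count", "heavy"} - set(table.columns)
    if missing:
        raise ValueError(f"peptide table lacks required columns: {sorted(missing)}")
    return table


def filter_peptides(
    table: pd.DataFrame,
    regulon_map: dict[str, frozenset],
    aliases: dict | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep arginine-containing, compartment-specific peptides.

    Returns the retained peptides (with a ``compartment`` and a primary
    ``regulon`` column) and a :class:`FilterReport` accounting for every
    input row: no-arginine peptides are excluded first, then peptides from
    vegetative, ambiguous or unmapped proteins.
    """
    table = _canonicalize(table, aliases)
    arg = table["arg_count"].to_numpy() >= 1
    compartments = np.array(
        [assign_compartment(p, regulon_map).compartment for p in table["protein_id"]]
    )
    n_unknown_prot = int((compartments == "unknown")[arg].sum())
    if n_unknown_prot:
        warnings.warn(
            f"{n_unknown_prot} arginine-containing peptides from proteins "
            "absent from the regulon map were excluded",
            stacklevel=2,
        )
    keep = arg & np.isin(compartments, ["mother_cell", "forespore"])
    kept = table.loc[keep].copy()
    kept["compartment"] = compartments[keep]

    def primary_regulon(pid: str) -> str:
        regs = regulon_map.get(pid, frozenset())
        specific = sorted(regs & (FORESPORE_REGULONS | MOTHER_CELL_REGULONS))
        return specific[0] if specific else ""

    kept["regulon"] = [primary_regulon(p) for p in kept["protein_id"]]
    report = FilterReport(
        n_input=len(table),
        n_no_arginine=int((~arg).sum()),
        n_vegetative=int((compartments == "vegetative")[arg].sum()),
        n_ambiguous=int((compartments == "ambiguous")[arg].sum()),
        n_unknown=n_unknown_prot,
        n_mother_cell=int((compartments == "mother_cell")[arg].sum()),
        n_forespore=int((compartments == "forespore")[arg].sum()),
    )
    return kept, report


def _wilson_row(group_type: str, group: str, heavy: np.ndarray) -> dict:
    n = int(len(heavy))
    h = int(np.asarray(heavy, dtype=bool).sum())
    low, high = proportion_confint(h, n, alpha=0.05, method="wilson")
    return {
        "group_type": group_type,
        "group": group,
        "n_peptides": n,
        "n_heavy": h,
        "fraction": h / n,
        "ci_low": float(low),
        "ci_high": float(high),
    }


def incorporation_summary(peptides: pd.DataFrame) -> IncorporationSummary:
    """Heavy-arginine fractions per compartment and per sporulation regulon.

    The regulon stratification separates proteins made during engulfment
    (SigF for the forespore, SigE for the mother cell) from those made
    after its completion (SigG, SigK). Empty compartments are omitted with
    a warning.
    """
    rows = []
    for comp in ("mother_cell", "forespore"):
        sub = peptides[peptides["compartment"] == comp]
        if sub.empty:
            warnings.warn(f"no peptides in compartment {comp!r}; omitted", stacklevel=2)
            continue
        rows.append(_wilson_row("compartment", comp, sub["heavy"].to_numpy()))
    if "regulon" in peptides.columns:
        for reg in ("SigE", "SigK", "SigF", "SigG"):
            sub = peptides[peptides["regulon"] == reg]
            if sub.empty:
                continue
            rows.append(_wilson_row("regulon", reg, sub["heavy"].to_numpy()))
    if not rows:
        raise ValueError("no compartment-specific peptides to summarize")
    return IncorporationSummary(table=pd.DataFrame(rows))


def fold_change(
    summary: IncorporationSummary, control: IncorporationSummary
) -> pd.DataFrame:
    """Per-group incorporation fold over a control scenario.

    The interval is the conservative ratio of Wilson bounds (lower bound
    over the control's upper, and vice versa). A zero control fraction
    leaves the fold undefined (NaN) with ``defined = False``.
    """
    rows = []
    ctrl = control.table.set_index(["group_type", "group"])
    for _, row in summary.table.iterrows():
        key = (row["group_type"], row["group"])
        if key not in ctrl.index:
            continue
        c = ctrl.loc[key]
        defined = c["fraction"] > 0
        rows.append(
            {
                "group_type": key[0],
                "group": key[1],
                "fold": row["fraction"] / c["fraction"] if defined else np.nan,
                "fold_low": row["ci_low"] / c["ci_high"]
                if defined and c["ci_high"] > 0
                else np.nan,
                "fold_high": row["ci_high"] / c["ci_low"]
                if defined and c["ci_low"] > 0
                else np.inf,
                "defined": bool(defined),
            }
        )
    return pd.DataFrame(rows)


def summarize_table(
    table: pd.DataFrame,
    regulon_map: dict[str, frozenset],
    control_table: pd.DataFrame | None = None,
    aliases: dict | None = None,
):
    """End-to-end convenience: filter, summarize, optional fold-change.

    Returns ``(summary, report, folds)``; ``folds`` is None without a
    control table.
    """
    kept, report = filter_peptides(table, regulon_map, aliases)
    summary = incorporation_summary(kept)
    folds = None
    if control_table is not None:
        ctrl_kept, _ = filter_peptides(control_table, regulon_map, aliases)
        folds = fold_change(summary, incorporation_summary(ctrl_kept))
    return summary, report, folds
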