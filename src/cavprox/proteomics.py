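"""Protein-level LFQ table ingestion and pre-statistics processing.

The pipeline operates on MaxQuant ``proteinGroups``-style tab-separated
tables. Processing before any statistics follows the standard Perseus
recipe: removal of contaminant / reverse / site-only rows, log2
transformation, and a replicate-presence filter that retains a protein
only if it was identified in at least *k* replicates of at least one
(bait, condition) group. An optional Perseus-style down-shifted normal
imputation is provided but disabled by default.

A raw intensity of 0 means "not identified" (MaxQuant convention) and is
mapped to missing at read time; presence rules therefore operate on
identification, not on intensity magnitude.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BAITS = ("Cav1", "NES")
CONDITIONS = ("NT", "HYPO", "REC")

FLAG_COLUMNS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}
PROTEIN_ID_COLUMN = "Majority protein IDs"
LFQ_PREFIX = "LFQ intensity "


class InputError(ValueError):
    """Malformed input table or design."""


class ConfigError(ValueError):
    """Invalid configuration of a processing step."""


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample ids to (bait, condition, replicate).

    ``table`` has columns sample_id, bait, condition, replicate.
    NES is a cytoplasmic spatial-reference bait and appears only under
    the iso-osmotic NT condition.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "bait", "condition", "replicate"}
        if not required.issubset(t.columns):
            raise InputError(f"design needs columns {sorted(required)}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise InputError(f"duplicate sample ids: {dup}")
        bad_bait = set(t["bait"]) - set(BAITS)
        if bad_bait:
            raise InputError(f"unknown baits: {sorted(bad_bait)}")
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise InputError(f"unknown conditions: {sorted(bad_cond)}")
        nes = t[t["bait"] == "NES"]
        if len(nes) and set(nes["condition"]) != {"NT"}:
            raise InputError("NES reference must appear only under NT")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """(bait, condition) -> ordered sample ids."""
        out: dict[tuple[str, str], list[str]] = {}
        for _, row in self.table.iterrows():
            out.setdefault((row["bait"], row["condition"]), []).append(
                row["sample_id"]
            )
        return out

    def group_samples(self, bait: str, condition: str) -> list[str]:
        key = (bait, condition)
        groups = self.groups()
        if key not in groups:
            raise InputError(f"no samples for group {key}")
        return groups[key]

    @classmethod
    def from_layout(
        cls,
        groups: Sequence[tuple[str, str]] = (
            ("Cav1", "NT"),
            ("Cav1", "HYPO"),
            ("Cav1", "REC"),
            ("NES", "NT"),
        ),
        n_replicates: int = 3,
    ) -> "SampleDesign":
        rows = [
            {
                "sample_id": f"{bait}_{cond}_{rep}",
                "bait": bait,
                "condition": cond,
                "replicate": rep,
            }
            for bait, cond in groups
            for rep in range(1, n_replicates + 1)
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class IntensityTable:
    """Raw LFQ intensities (protein x sample) with row flags.

    ``intensities``: DataFrame indexed by protein id, one column per
    sample id, NaN encodes missing. ``flags``: boolean DataFrame with
    columns contaminant / reverse / only_by_site.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.flags.index):
            raise InputError("intensity and flag tables disagree on proteins")
        missing = set(self.design.sample_ids) - set(self.intensities.columns)
        if missing:
            raise InputError(f"design samples absent from table: {sorted(missing)}")
        vals = self.intensities.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise InputError("negative intensities")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class LogMatrix:
    """log2 intensities with an append-only provenance trail."""

    values: pd.DataFrame
    design: SampleDesign
    provenance: list[str] = field(default_factory=list)

    def with_step(self, values: pd.DataFrame, step: str) -> "LogMatrix":
        return LogMatrix(values, self.design, [*self.provenance, step])

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index


def read_protein_table(path: str | Path | io.TextIOBase, design: SampleDesign) -> IntensityTable:
    """Read a MaxQuant proteinGroups-dialect TSV.

    Raw zeros become missing. Flags are parsed from the '+' convention.
    Raises :class:`InputError` naming any design sample whose
    "LFQ intensity <sample>" column is absent, and on duplicate
    protein ids or unparseable numerics.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if PROTEIN_ID_COLUMN not in df.columns:
        raise InputError(f"missing column {PROTEIN_ID_COLUMN!r}")
    missing_cols = [
        s for s in design.sample_ids if LFQ_PREFIX + s not in df.columns
    ]
    if missing_cols:
        raise InputError(
            "missing LFQ intensity columns for samples: " + ", ".join(missing_cols)
        )
    ids = df[PROTEIN_ID_COLUMN]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].tolist()
        raise InputError(f"duplicate protein ids: {dup[:5]}")

    inten = {}
    for s in design.sample_ids:
        col = df[LFQ_PREFIX + s]
        try:
            vals = pd.to_numeric(col)
        except (ValueError, TypeError) as exc:
            raise InputError(f"unparseable value in column {LFQ_PREFIX + s!r}: {exc}")
        inten[s] = vals.where(vals != 0, np.nan)
    intensities = pd.DataFrame(inten)
    intensities.index = pd.Index(ids, name="protein_id")

    flags = pd.DataFrame(index=intensities.index)
    for name, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[name] = (df[col].fillna("") == "+").to_numpy()
        else:
            flags[name] = False
    return IntensityTable(intensities, flags, design)


def write_protein_table(table: IntensityTable, path: str | Path) -> None:
    """Write an IntensityTable back to the MaxQuant dialect (missing -> 0)."""
    out = pd.DataFrame({PROTEIN_ID_COLUMN: table.protein_ids})
    for s in table.design.sample_ids:
        out[LFQ_PREFIX + s] = table.intensities[s].fillna(0).to_numpy()
    for name, col in FLAG_COLUMNS.items():
        out[col] = np.where(table.flags[name].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)


def remove_flagged_rows(table: IntensityTable) -> IntensityTable:
    """Drop contaminant, reverse and identified-only-by-site rows."""
    keep = ~table.flags.any(axis=1)
    return IntensityTable(
        table.intensities.loc[keep], table.flags.loc[keep], table.design
    )


def log2_transform(table: IntensityTable) -> LogMatrix:
    """Element-wise log2; missing stays missing."""
    vals = table.intensities
    present = vals.notna()
    if (vals.where(present, 1.0) <= 0).any().any():
        raise InputError("nonpositive intensity present; cannot log2-transform")
    return LogMatrix(
        np.log2(vals),
        table.design,
        [f"log2_transform(n={len(vals)})"],
    )


def replicate_presence_filter(logmat: LogMatrix, k: int | None = None) -> LogMatrix:
    """Retain a protein iff some (bait, condition) group has >= k present values.

    Default k is each group's own replicate count (the "three out of
    three replicates of at least one sample" rule).
    """
    groups = logmat.design.groups()
    present = logmat.values.notna()
    keep = pd.Series(False, index=logmat.values.index)
    for (bait, cond), samples in groups.items():
        k_g = len(samples) if k is None else k
        if k_g > len(samples):
            raise ConfigError(
                f"k={k} exceeds replicate count {len(samples)} of group ({bait},{cond})"
            )
        keep |= present[samples].sum(axis=1) >= k_g
    rule = "all replicates" if k is None else f"k={k}"
    return logmat.with_step(
        logmat.values.loc[keep],
        f"replicate_presence_filter({rule}): {int(keep.sum())}/{len(keep)} retained",
    )


def impute_downshifted(
    logmat: LogMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | None = 0,
) -> LogMatrix:
    """Perseus-style per-sample down-shifted normal imputation.

    Missing values in column *s* are drawn from
    Normal(mean_s - shift * sd_s, (width * sd_s)^2) over the observed
    values of that column. Disabled by default in the pipeline; exists
    so that contrasts with an all-missing group become testable.
    """
    rng = np.random.default_rng(seed)
    vals = logmat.values.copy()
    n_imputed = 0
    for s in vals.columns:
        col = vals[s]
        observed = col.dropna()
        miss = col.isna()
        if not miss.any():
            continue
        if len(observed) < 2:
            raise ConfigError(f"column {s!r} has < 2 present values; cannot impute")
        mu, sd = observed.mean(), observed.std(ddof=1)
        draw = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
        vals.loc[miss, s] = draw
        n_imputed += int(miss.sum())
    return logmat.with_step(
        vals,
        f"impute_downshifted(width={width}, shift={shift}, seed={seed}): "
        f"{n_imputed} values imputed",
    )
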