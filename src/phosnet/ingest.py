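"""Reading, merging and pre-filtering of MaxQuant-dialect phosphosite tables.

The unit of quantification is the phosphosite: a phosphorylated S/T/Y
residue at a 1-based position on a protein, carried by a peptide form of a
given multiplicity (number of phosphate groups, 1-3).  MaxQuant's
``Phospho (STY)Sites.txt`` stores one row per (protein, position) and
splits the quantification over intensity columns suffixed ``___1``,
``___2``, ``___3`` — one slice per multiplicity.  Here every
(protein_id, position, residue, multiplicity) combination becomes one
record, keyed uniquely after merging replicate files.

An intensity of 0 means "not detected"; blank cells are treated the same
way.  A (row, multiplicity) slice whose cells are all blank yields no
record at all — the file simply does not carry that peptide form.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Order of the fields forming the unique site key.
SITE_INDEX = ["protein_id", "position", "residue", "multiplicity"]

#: Columns a sample-design table must provide.
DESIGN_COLUMNS = ["sample_column", "condition", "time_min", "replicate"]

# Header aliases, matched case-insensitively: MaxQuant versions rename
# these between releases.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "protein_id": ("protein", "proteins", "protein id", "leading proteins"),
    "position": ("position", "positions within proteins"),
    "residue": ("amino acid", "aminoacid"),
    "localization_prob": ("localization prob", "localization probability"),
    "is_reverse": ("reverse",),
    "is_contaminant": ("potential contaminant", "contaminant"),
}

_MULT_SUFFIX = re.compile(r"^(?P<base>.+)___(?P<mult>[123])$")


class ColumnError(ValueError):
    """A mandatory column is missing or an intensity column is unmapped."""


@dataclass
class PhosphoTable:
    """Site-by-sample intensity matrix with its sample design.

    Attributes
    ----------
    intensities
        DataFrame indexed by the (protein_id, position, residue,
        multiplicity) MultiIndex, one column per sample; values are
        non-negative, 0 encoding "not detected".
    design
        DataFrame indexed by sample name with columns ``condition``,
        ``time_min`` and ``replicate``.  (condition, time_min, replicate)
        is unique.
    meta
        Per-site metadata: ``localization_prob``, ``is_contaminant``,
        ``is_reverse``; same index as ``intensities``.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "localization_prob": 1.0,
                    "is_contaminant": False,
                    "is_reverse": False,
                },
                index=self.intensities.index,
            )
        self._validate()

    def _validate(self) -> None:
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate site keys: {list(dup[:5])!r}")
        if self.design.index.has_duplicates:
            raise ValueError("duplicate sample names in design")
        key = self.design[["condition", "time_min", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(condition, time_min, replicate) not unique in design")
        missing = set(self.intensities.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"intensity columns without design entry: {sorted(missing)}")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy() < 0).any():
                raise ValueError("negative intensities")

    @property
    def n_sites(self) -> int:
        return len(self.intensities)

    @property
    def conditions(self) -> list:
        return sorted(self.design["condition"].unique())

    @property
    def times(self) -> list:
        return sorted(self.design["time_min"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.design["replicate"].unique())

    def copy(self) -> "PhosphoTable":
        return PhosphoTable(
            self.intensities.copy(), self.design.copy(), self.meta.copy()
        )


def read_design(path) -> pd.DataFrame:
    """Read a sample-design TSV (sample_column, condition, time_min, replicate)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnError(f"design table missing column(s): {missing}")
    df = df.set_index("sample_column")
    df["time_min"] = df["time_min"].astype(float)
    return df


def _resolve_columns(columns, aliases) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    resolved = {}
    for field_name, names in aliases.items():
        for name in names:
            if name in lower:
                resolved[field_name] = lower[name]
                break
    return resolved


def _truthy_flag(series: pd.Series) -> pd.Series:
    """MaxQuant marks flags with '+'; accept booleans and 0/1 too."""
    s = series.fillna("").astype(str).str.strip().str.lower()
    return s.isin(("+", "true", "1", "yes"))


def read_phospho_table(
    path,
    design: pd.DataFrame,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> PhosphoTable:
    """Parse one Phospho(STY)-dialect TSV into a :class:`PhosphoTable`.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    design
        Sample design whose index gives the base intensity column names
        (multiplicity suffixes ``___1..3`` are resolved automatically).
    aliases
        Optional override of the case-insensitive header aliases.

    Raises
    ------
    ColumnError
        If a mandatory column is missing, or an intensity-like column
        (``...___k``) has no design match.
    """
    aliases = {**DEFAULT_ALIASES, **(aliases or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    resolved = _resolve_columns(raw.columns, aliases)
    mandatory = ["protein_id", "position", "residue", "localization_prob"]
    for f in mandatory:
        if f not in resolved:
            raise ColumnError(f"missing mandatory column for field {f!r}")

    lower_cols = {c.lower(): c for c in raw.columns}
    design_lower = {str(s).lower(): s for s in design.index}

    # Map design samples to their per-multiplicity file columns.
    sample_cols: dict[object, dict[int, str]] = {s: {} for s in design.index}
    orphans = []
    for col in raw.columns:
        m = _MULT_SUFFIX.match(col)
        if not m:
            continue
        base = m.group("base").lower().strip()
        if base in design_lower:
            sample_cols[design_lower[base]][int(m.group("mult"))] = col
        else:
            orphans.append(col)
    if orphans:
        raise ColumnError(f"intensity columns with no design match: {orphans}")
    unmapped = [s for s, cols in sample_cols.items() if not cols]
    # Fall back to bare (unsuffixed) columns, treated as multiplicity 1.
    for s in list(unmapped):
        bare = lower_cols.get(str(s).lower())
        if bare is not None:
            sample_cols[s][1] = bare
            unmapped.remove(s)
    if unmapped:
        raise ColumnError(f"design samples with no intensity column: {unmapped}")

    multiplicities = sorted({m for cols in sample_cols.values() for m in cols})

    def _num(series: pd.Series) -> np.ndarray:
        # float() round-trips repr() exactly; pd.to_numeric may be off
        # by one ulp, which would break bit-exact write/read cycles
        s = series.replace("", "0")
        return np.fromiter((float(v) for v in s), dtype=float, count=len(s))

    frames = []
    for mult in multiplicities:
        cols = {s: sample_cols[s].get(mult) for s in design.index}
        present = {s: c for s, c in cols.items() if c is not None}
        if not present:
            continue
        block = raw[[c for c in present.values()]]
        all_blank = (block == "").all(axis=1)
        vals = pd.DataFrame(
            {s: _num(raw[c]) for s, c in present.items()}, index=raw.index
        )
        for s in design.index:
            if s not in vals.columns:
                vals[s] = 0.0
        vals = vals[list(design.index)]
        sub = pd.DataFrame(
            {
                "protein_id": raw[resolved["protein_id"]].str.strip(),
                "position": pd.to_numeric(raw[resolved["position"]]).astype(int),
                "residue": raw[resolved["residue"]].str.strip(),
                "multiplicity": mult,
                "localization_prob": pd.to_numeric(
                    raw[resolved["localization_prob"]].replace("", "nan")
                ),
            }
        )
        if "is_contaminant" in resolved:
            sub["is_contaminant"] = _truthy_flag(raw[resolved["is_contaminant"]])
        else:
            sub["is_contaminant"] = False
        if "is_reverse" in resolved:
            sub["is_reverse"] = _truthy_flag(raw[resolved["is_reverse"]])
        else:
            sub["is_reverse"] = False
        keep = ~all_blank
        frames.append((sub[keep], vals[keep.to_numpy()]))

    if not frames or all(len(f[0]) == 0 for f in frames):
        empty_idx = pd.MultiIndex.from_arrays([[], [], [], []], names=SITE_INDEX)
        return PhosphoTable(
            pd.DataFrame(columns=list(design.index), index=empty_idx, dtype=float),
            design.copy(),
            pd.DataFrame(
                columns=["localization_prob", "is_contaminant", "is_reverse"],
                index=empty_idx,
            ),
        )

    meta = pd.concat([f[0] for f in frames], ignore_index=True)
    inten = pd.concat([f[1] for f in frames], ignore_index=True)

    _check_positions(meta)
    idx = pd.MultiIndex.from_frame(meta[SITE_INDEX])
    if idx.has_duplicates:
        dup = idx[idx.duplicated()]
        raise ValueError(f"duplicate site keys within one file: {list(dup[:5])!r}")
    inten.index = idx
    meta_out = meta[["localization_prob", "is_contaminant", "is_reverse"]].set_axis(
        idx, axis=0
    )
    return PhosphoTable(inten, design.copy(), meta_out)


def _check_positions(meta: pd.DataFrame) -> None:
    if (meta["position"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    bad = ~meta["residue"].isin(("S", "T", "Y"))
    if bad.any():
        raise ValueError(
            f"unexpected residues: {sorted(meta.loc[bad, 'residue'].unique())}"
        )
    probs = meta["localization_prob"]
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("localization probabilities must lie in [0, 1]")


def merge_replicate_tables(tables: list[PhosphoTable]) -> PhosphoTable:
    """Merge per-replicate tables on the (protein, position, residue,
    multiplicity) key.

    Sites present in several files are merged into one record whose
    intensity map is the union over samples; sites missing from a file get
    0 ("not detected") in that file's samples.  Localization probabilities
    are combined by maximum and contaminant/reverse flags by logical OR.

    Raises
    ------
    ValueError
        If two tables share a sample name or a (condition, time,
        replicate) design key.
    """
    if not tables:
        raise ValueError("no tables to merge")
    if len(tables) == 1:
        return tables[0].copy()

    seen_samples: set = set()
    seen_keys: set = set()
    for t in tables:
        overlap = seen_samples & set(t.design.index)
        if overlap:
            raise ValueError(f"colliding sample names across tables: {sorted(overlap)}")
        keys = set(map(tuple, t.design[["condition", "time_min", "replicate"]].values))
        if seen_keys & keys:
            raise ValueError("colliding (condition, time, replicate) keys across tables")
        seen_samples |= set(t.design.index)
        seen_keys |= keys

    design = pd.concat([t.design for t in tables])
    inten = pd.concat([t.intensities for t in tables], axis=1).fillna(0.0)
    # Union index may hold duplicates only if an input did; PhosphoTable checks.
    metas = pd.concat([t.meta for t in tables])
    grouped = metas.groupby(level=list(range(len(SITE_INDEX))), sort=False)
    meta = pd.DataFrame(
        {
            "localization_prob": grouped["localization_prob"].max(),
            "is_contaminant": grouped["is_contaminant"].any(),
            "is_reverse": grouped["is_reverse"].any(),
        }
    )
    meta = meta.reindex(inten.index)
    return PhosphoTable(inten, design, meta)


def apply_site_filters(
    table: PhosphoTable, min_localization: float = 0.75
) -> PhosphoTable:
    """Remove contaminant/reverse hits and poorly localized sites.

    Sites with ``localization_prob`` strictly below ``min_localization``
    are dropped; sites exactly at the threshold are retained
    (localization probability >= 0.75 is the high-confidence gate).
    Idempotent.
    """
    meta = table.meta
    prob = meta["localization_prob"].fillna(0.0)
    keep = (~meta["is_contaminant"]) & (~meta["is_reverse"]) & (
        prob >= min_localization
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "site filters removed %d of %d sites (contaminant/reverse/localization)",
            n_drop,
            len(keep),
        )
    return PhosphoTable(
        table.intensities.loc[keep].copy(),
        table.design.copy(),
        table.meta.loc[keep].copy(),
    )
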