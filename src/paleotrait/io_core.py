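"""Data model, file I/O and climatic-period classification.

The pipeline operates on three tables:

* a **read matrix** — non-negative integer metabarcoding read counts,
  samples (rows) by MOTUs (columns);
* a **sample table** — per-sample metadata: site, coordinates (decimal
  degrees), radiocarbon age in thousands of years before present (ka BP),
  and the derived climatic period;
* a **trait table** — one categorical record per MOTU for five traits:
  growth form, mycorrhizal type, mycorrhizal status, N-fixation and
  pollination mode.

Samples are binned into three climatic periods relevant to unglaciated
northern high latitudes: pre-LGM (older than 25 ka BP, stadial–interstadial
fluctuations), LGM (25–15 ka BP, cold and arid) and post-LGM (younger than
15 ka BP, the transition into the Holocene).
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PERIODS",
    "TRAITS",
    "TRAIT_LEVELS",
    "ParseError",
    "ValidationError",
    "assign_period",
    "assign_periods",
    "validate_sample_table",
    "validate_read_matrix",
    "validate_trait_table",
    "check_nm_consistency",
    "read_dataset",
    "write_dataset",
    "load_config",
]

#: Climatic periods, oldest first.
PERIODS = ("pre-LGM", "LGM", "post-LGM")

#: The five categorical traits, in canonical order.
TRAITS = ("growth_form", "myc_type", "myc_status", "n_fix", "pollination")

#: Canonical category labels per trait ("undefined" is an explicit level).
TRAIT_LEVELS: dict[str, tuple[str, ...]] = {
    "growth_form": ("forb", "graminoid", "dwarf_shrub", "tree_shrub", "undefined"),
    "myc_type": ("AM", "ECM", "ERM", "NM", "undefined"),
    "myc_status": ("OM", "FM", "NM", "undefined"),
    "n_fix": ("fixer", "nonfixer", "undefined"),
    "pollination": ("insect", "wind", "undefined"),
}

SAMPLE_COLUMNS = ("sample_id", "site_id", "latitude", "longitude", "age", "period")


class ParseError(ValueError):
    """A file could not be parsed into a valid table; message names the locus."""


class ValidationError(ValueError):
    """A table violates an invariant of the data model."""


def assign_period(age: float) -> str:
    """Classify an age in ka BP into pre-LGM / LGM / post-LGM.

    Intervals are ``(25, inf) -> pre-LGM``, ``(15, 25] -> LGM`` and
    ``[0, 15] -> post-LGM``; the upper boundary of each interval belongs to
    the younger period.

    Raises
    ------
    ValidationError
        If ``age`` is negative or not finite.
    """
    if not np.isfinite(age) or age < 0:
        raise ValidationError(f"age must be a finite non-negative ka BP value, got {age!r}")
    if age > 25:
        return "pre-LGM"
    if age > 15:
        return "LGM"
    return "post-LGM"


def assign_periods(ages: Iterable[float]) -> pd.Series:
    """Vectorised :func:`assign_period` over an iterable of ages."""
    ages = pd.Series(list(ages), dtype=float)
    if (~np.isfinite(ages)).any() or (ages < 0).any():
        bad = ages[(~np.isfinite(ages)) | (ages < 0)]
        raise ValidationError(f"invalid ages at positions {list(bad.index)}")
    out = pd.Series(np.where(ages > 25, "pre-LGM", np.where(ages > 15, "LGM", "post-LGM")))
    out.index = ages.index
    return out


def _canonical_level_map() -> dict[str, dict[str, str]]:
    return {t: {lv.lower(): lv for lv in levels} for t, levels in TRAIT_LEVELS.items()}


_CANON = _canonical_level_map()


def normalize_trait_value(trait: str, value, *, locus: str = "") -> str:
    """Trim/case-fold a raw trait cell to its canonical level.

    Missing values (NaN, empty string) map to ``"undefined"``. Unknown
    levels raise :class:`ParseError` naming the offending cell.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "undefined"
    s = str(value).strip()
    if not s:
        return "undefined"
    canon = _CANON[trait].get(s.lower())
    if canon is None:
        where = f" at {locus}" if locus else ""
        raise ParseError(f"unknown level {s!r} for trait {trait!r}{where}")
    return canon


def validate_sample_table(st: pd.DataFrame) -> pd.DataFrame:
    """Validate (and return) a sample table.

    Checks unique sample ids, coordinate ranges, non-negative ages, and that
    the ``period`` column is consistent with ``age`` under the
    classification rule (a missing period column is derived from age).
    """
    st = st.copy()
    missing = [c for c in SAMPLE_COLUMNS if c not in st.columns and c != "period"]
    if missing:
        raise ValidationError(f"sample table missing columns {missing}")
    if st["sample_id"].duplicated().any():
        dups = st.loc[st["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids {dups}")
    if ((st["latitude"] < -90) | (st["latitude"] > 90)).any():
        raise ValidationError("latitude out of [-90, 90]")
    if ((st["longitude"] < -180) | (st["longitude"] > 180)).any():
        raise ValidationError("longitude out of [-180, 180]")
    expected = assign_periods(st["age"])
    if "period" not in st.columns:
        st["period"] = expected.to_numpy()
    else:
        mism = st.loc[st["period"].to_numpy() != expected.to_numpy(), "sample_id"]
        if len(mism):
            raise ValidationError(f"period inconsistent with age for samples {list(mism)}")
    return st


def validate_read_matrix(rm: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x MOTUs read-count matrix (integer, non-negative)."""
    if rm.index.duplicated().any():
        raise ValidationError(f"duplicate sample ids {rm.index[rm.index.duplicated()].tolist()}")
    if rm.columns.duplicated().any():
        raise ValidationError(f"duplicate MOTU ids {rm.columns[rm.columns.duplicated()].tolist()}")
    vals = rm.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ParseError("read matrix contains non-numeric entries")
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ParseError(f"negative count at sample {rm.index[i]!r}, MOTU {rm.columns[j]!r}")
    if not np.allclose(vals, np.round(vals)):
        raise ParseError("read matrix contains non-integer counts")
    return rm.astype(np.int64)


def validate_trait_table(tt: pd.DataFrame, *, normalize: bool = True) -> pd.DataFrame:
    """Validate a trait table indexed by motu_id; optionally normalise levels."""
    if tt.index.duplicated().any():
        raise ValidationError(f"duplicate MOTU ids {tt.index[tt.index.duplicated()].tolist()}")
    missing = [t for t in TRAITS if t not in tt.columns]
    if missing:
        raise ValidationError(f"trait table missing columns {missing}")
    tt = tt.copy()
    for t in TRAITS:
        if normalize:
            tt[t] = [
                normalize_trait_value(t, v, locus=f"motu {m!r}, column {t!r}")
                for m, v in tt[t].items()
            ]
        else:
            bad = ~tt[t].isin(TRAIT_LEVELS[t])
            if bad.any():
                raise ParseError(
                    f"unknown level {tt.loc[bad, t].iloc[0]!r} for trait {t!r} "
                    f"at motu {tt.index[bad][0]!r}"
                )
    check_nm_consistency(tt)
    return tt[list(TRAITS)]


def check_nm_consistency(tt: pd.DataFrame) -> None:
    """Enforce NM type <=> NM status whenever both are defined."""
    both = (tt["myc_type"] != "undefined") & (tt["myc_status"] != "undefined")
    bad = both & ((tt["myc_type"] == "NM") != (tt["myc_status"] == "NM"))
    if bad.any():
        raise ValidationError(
            "NM mycorrhizal type/status inconsistent for MOTUs "
            f"{tt.index[bad].tolist()}"
        )


DEFAULT_CONFIG: dict = {
    "read_matrix": {"delimiter": "\t", "index_col": "sample_id"},
    "samples": {"delimiter": ",", "columns": {}},
    "traits": {"delimiter": ",", "columns": {}, "index_col": "motu_id"},
}


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML format-configuration (column-name mapping, delimiters)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = {k: {**v} for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        merged.setdefault(k, {}).update(v or {})
    return merged


def read_dataset(
    matrix_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    traits_path: str | os.PathLike,
    config: Mapping | str | os.PathLike | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read (ReadMatrix, SampleTable, TraitTable) from disk.

    The read matrix is a wide TSV whose first column is ``sample_id``; the
    sample and trait tables are CSV. ``config`` may rename columns and
    override delimiters. Label consistency is checked: every read-matrix row
    must appear in the sample table and every column in the trait table.
    """
    if config is None:
        cfg = DEFAULT_CONFIG
    elif isinstance(config, (str, os.PathLike)):
        cfg = load_config(config)
    else:
        cfg = {k: {**DEFAULT_CONFIG.get(k, {}), **dict(v)} for k, v in config.items()}
        for k in DEFAULT_CONFIG:
            cfg.setdefault(k, dict(DEFAULT_CONFIG[k]))

    rm = pd.read_csv(matrix_path, sep=cfg["read_matrix"]["delimiter"], index_col=0)
    rm.index.name = "sample_id"
    rm = validate_read_matrix(rm)

    st = pd.read_csv(samples_path, sep=cfg["samples"]["delimiter"])
    if cfg["samples"].get("columns"):
        st = st.rename(columns=cfg["samples"]["columns"])
    st = validate_sample_table(st)

    tt = pd.read_csv(traits_path, sep=cfg["traits"]["delimiter"])
    if cfg["traits"].get("columns"):
        tt = tt.rename(columns=cfg["traits"]["columns"])
    idx = cfg["traits"].get("index_col", "motu_id")
    if idx in tt.columns:
        tt = tt.set_index(idx)
    tt.index.name = "motu_id"
    tt = validate_trait_table(tt)

    missing_samples = set(rm.index) - set(st["sample_id"])
    if missing_samples:
        raise ValidationError(f"read-matrix samples absent from sample table: {sorted(missing_samples)}")
    missing_motus = set(rm.columns) - set(tt.index)
    if missing_motus:
        raise ValidationError(f"read-matrix MOTUs absent from trait table: {sorted(missing_motus)}")
    return rm, st, tt


def write_dataset(
    outdir: str | os.PathLike,
    rm: pd.DataFrame,
    st: pd.DataFrame,
    tt: pd.DataFrame,
) -> dict[str, str]:
    """Write the three tables as UTF-8, LF-terminated TSV/CSV; return paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "read_matrix": os.path.join(outdir, "read_matrix.tsv"),
        "samples": os.path.join(outdir, "samples.csv"),
        "traits": os.path.join(outdir, "traits.csv"),
    }
    _to_text(rm, paths["read_matrix"], sep="\t", index=True, index_label="sample_id")
    _to_text(st, paths["samples"], sep=",", index=False)
    _to_text(tt, paths["traits"], sep=",", index=True, index_label="motu_id")
    return paths


def _to_text(df: pd.DataFrame, path: str, **kw) -> None:
    buf = io.StringIO()
    df.to_csv(buf, lineterminator="\n", **kw)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
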