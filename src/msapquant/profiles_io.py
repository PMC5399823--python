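"""I/O for binary MSAP marker matrices and four-bit code counts.

An MSAP experiment on paired control/stressed material produces four binary
presence/absence tracks per marker and sample: EcoRI/HpaII and EcoRI/MspI
digests of the control, and the same two digests of the stressed
counterpart.  This module reads such tracks from tab-delimited text,
harmonises them into an :class:`ExperimentBundle`, and reduces them to
per-sample counts of the sixteen four-bit codes — the sole input the
quantification step needs.  A pre-tallied code-count table (codes x
samples) is accepted as an alternative entry point.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .site_model import ALL_CODES, parse_code

__all__ = [
    "MarkerMatrix",
    "ExperimentBundle",
    "ParseError",
    "ValidationError",
    "read_matrix",
    "write_matrix",
    "extract_codes",
    "load_code_counts",
    "write_code_counts",
    "read_bundle_manifest",
    "load_triticale_dataset",
    "TRACK_NAMES",
]

logger = logging.getLogger("msapquant")
if not logger.handlers:  # default to stderr, as a CLI tool should
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ParseError(ValueError):
    """A file could not be parsed as the expected tabular format."""


class ValidationError(ValueError):
    """Parsed data violate a contract (duplicates, mismatched sets, ...)."""


MISSING_TOKENS = {"NA", "na", "NaN", "nan", ""}

#: Canonical track order: bit order of the four-bit code.
TRACK_NAMES: tuple[str, ...] = (
    "control_hpa", "control_msp", "stressed_hpa", "stressed_msp",
)


@dataclass
class MarkerMatrix:
    """A markers x samples presence/absence matrix.

    ``data`` holds floats with NaN for explicit missing calls; all observed
    values are strictly 0 or 1.
    """

    data: pd.DataFrame

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def read_matrix(path) -> MarkerMatrix:
    """Read a binary marker matrix from tab-delimited text.

    First column: marker identifiers; header row: sample identifiers; cells
    in {0, 1, NA}.  Lines starting with ``#`` are provenance comments and
    are skipped.  Non-binary cells are reported with their row/column
    coordinates; duplicate marker or sample identifiers are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         comment="#", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate marker ids {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    out = pd.DataFrame(index=df.index.astype(str),
                       columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            cell = str(raw).strip()
            if cell in ("0", "1"):
                out.iat[i, j] = float(cell)
            elif cell in MISSING_TOKENS:
                out.iat[i, j] = np.nan
            else:
                raise ParseError(
                    f"{path}: non-binary cell {raw!r} at marker "
                    f"{df.index[i]!r}, sample {col!r} (row {i + 2}, "
                    f"column {j + 2})"
                )
    return MarkerMatrix(out)


def write_matrix(matrix: MarkerMatrix, path, header_lines: Iterable[str] = ()) -> None:
    """Write a marker matrix as tab-delimited text (NaN as ``NA``)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df = matrix.data.astype("Int64")
        df.index.name = "marker"
        df.to_csv(fh, sep="\t", na_rep="NA")


@dataclass
class ExperimentBundle:
    """Four harmonised marker matrices: control/stressed x HpaII/MspI."""

    control_hpa: MarkerMatrix
    control_msp: MarkerMatrix
    stressed_hpa: MarkerMatrix
    stressed_msp: MarkerMatrix

    def tracks(self) -> dict[str, MarkerMatrix]:
        return {name: getattr(self, name) for name in TRACK_NAMES}

    def __post_init__(self) -> None:
        ref = self.control_hpa.data
        for name, track in self.tracks().items():
            d = track.data
            if set(d.index) != set(ref.index) or set(d.columns) != set(ref.columns):
                missing_m = sorted(set(ref.index) ^ set(d.index))
                missing_s = sorted(set(ref.columns) ^ set(d.columns))
                raise ValidationError(
                    f"track {name!r} does not match control_hpa: "
                    f"marker set difference {missing_m[:10]}, "
                    f"sample set difference {missing_s[:10]}"
                )
            # harmonise ordering to the control_hpa track
            track.data = d.loc[ref.index, ref.columns]

    @property
    def marker_ids(self) -> list[str]:
        return self.control_hpa.marker_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.control_hpa.sample_ids


def extract_codes(bundle: ExperimentBundle) -> pd.DataFrame:
    """Reduce a bundle to per-sample counts of the sixteen four-bit codes.

    For each marker and sample the code is the concatenation
    (control-HpaII, control-MspI, stressed-HpaII, stressed-MspI).  Markers
    with a missing call in any track are excluded for that sample, with the
    tally logged to standard error.  Returns a 16 x n_samples integer
    DataFrame indexed by code.
    """
    arrays = [bundle.tracks()[name].data.to_numpy(dtype=float)
              for name in TRACK_NAMES]
    stack = np.stack(arrays, axis=-1)  # markers x samples x 4
    valid = ~np.isnan(stack).any(axis=-1)  # markers x samples
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("extract_codes: dropped %d marker/sample calls with "
                    "missing values", n_dropped)
    bits = np.nan_to_num(stack, nan=0.0).astype(np.int64)
    code_idx = (bits[..., 0] * 8 + bits[..., 1] * 4
                + bits[..., 2] * 2 + bits[..., 3])
    counts = np.zeros((16, len(bundle.sample_ids)), dtype=np.int64)
    for j in range(len(bundle.sample_ids)):
        idx = code_idx[valid[:, j], j]
        counts[:, j] = np.bincount(idx, minlength=16)
    out = pd.DataFrame(counts, index=list(ALL_CODES),
                       columns=bundle.sample_ids)
    out.index.name = "code"
    retained = valid.sum(axis=0)
    for j, sample in enumerate(bundle.sample_ids):
        assert out[sample].sum() == retained[j]
    logger.info("extract_codes: retained marker counts per sample: %s",
                dict(zip(bundle.sample_ids, retained.tolist())))
    return out


def load_code_counts(path) -> pd.DataFrame:
    """Read a pre-tallied code-count table (rows: four-bit codes, columns:
    samples).  Codes absent from the file default to count 0; the result
    always has all sixteen rows in canonical order."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no code rows / sample columns found")
    codes = [parse_code(c) for c in df.index]
    if len(set(codes)) != len(codes):
        raise ValidationError(f"{path}: duplicate code rows")
    counts = pd.DataFrame(0, index=list(ALL_CODES),
                          columns=df.columns.astype(str), dtype=np.int64)
    for code, row in zip(codes, df.itertuples(index=False)):
        vals = np.asarray(row, dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise ParseError(
                f"{path}: counts for code {code} must be non-negative "
                "integers"
            )
        counts.loc[code] = vals.astype(np.int64)
    counts.index.name = "code"
    return counts


def write_code_counts(counts: pd.DataFrame, path,
                      header_lines: Iterable[str] = (),
                      drop_empty: bool = False) -> None:
    """Write a code-count table as tab-delimited text."""
    df = counts
    if drop_empty:
        df = df.loc[(df != 0).any(axis=1)]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_bundle_manifest(path) -> ExperimentBundle:
    """Read a four-track bundle via a flat ``key=value`` manifest naming the
    four matrix files (keys ``control_hpa``, ``control_msp``,
    ``stressed_hpa``, ``stressed_msp``; relative paths are resolved against
    the manifest's directory)."""
    from pathlib import Path

    base = Path(path).parent
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            entries[key.strip()] = value.strip()
    missing = [k for k in TRACK_NAMES if k not in entries]
    if missing:
        raise ValidationError(f"{path}: manifest missing keys {missing}")
    tracks = {k: read_matrix(base / entries[k]) for k in TRACK_NAMES}
    return ExperimentBundle(**tracks)


def load_triticale_dataset() -> tuple[pd.DataFrame, pd.Series]:
    """The packaged aluminium-stress triticale dataset: four-bit code counts
    for five Al-tolerant (T1–T5) and five non-tolerant (NT1–NT5) inbred
    lines, plus the sample -> group map."""
    pkg = resources.files("msapquant") / "data"
    counts = load_code_counts(pkg / "triticale_al_code_counts.tsv")
    groups_df = pd.read_csv(pkg / "triticale_al_groups.tsv", sep="\t",
                            index_col=0)
    return counts, groups_df["group"]
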