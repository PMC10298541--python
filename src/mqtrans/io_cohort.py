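"""Cohort input/output: expression matrices, platform annotation, TF registries
and metastasis-label curation.

The expected on-disk dialects are plain tab-separated text:

* expression matrix — first column feature IDs, header row sample IDs,
  log2-scale intensities (missing cells allowed, encoded as empty or ``NA``);
* platform annotation — columns ``probe_id`` and ``gene_symbols``, the latter
  a ``///``-delimited symbol list (possibly empty), mirroring the Affymetrix
  GPL570 annotation style;
* TF registry — one gene symbol per line (AnimalTFDB-style flat list);
* sample metadata — columns ``sample_id``, ``m_parameter``,
  ``metastasis_date``, ``diagnosis``.

Matrices are assumed already normalized/log-scaled as distributed; no
renormalization is applied here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "FeatureClass",
    "SampleAnnotation",
    "FeaturePartition",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_platform_annotation",
    "read_tf_registry",
    "read_sample_metadata",
    "curate_labels",
    "partition_features",
    "DEFAULT_METASTASIS_KEYWORDS",
]

_NA_STRINGS = {"", "na", "nan", "null", "none", "n/a"}

#: Diagnosis keywords taken to indicate a distant metastatic organ.  The
#: literature gives no canonical lexicon, so the list is configurable; these
#: defaults cover the common distant sites of colon cancer.
DEFAULT_METASTASIS_KEYWORDS: tuple[str, ...] = (
    "metasta",  # metastasis / metastatic / metastases
    "liver",
    "hepatic",
    "lung",
    "pulmonary",
    "peritone",
    "bone",
    "brain",
    "distant",
)


class Label(str, enum.Enum):
    """Curated metastasis status of a sample."""

    PRIMARY = "primary"
    METASTATIC = "metastatic"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FeatureClass(str, enum.Enum):
    """Role of a probe in the regression design."""

    TF = "TF"
    MRNA = "mRNA"
    UNMAPPED = "unmapped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metastasis evidence and the derived label.

    A sample is *metastatic* if its TNM M parameter exceeds 0, a metastasis
    date is recorded, or the diagnosis text names a distant metastatic organ.
    A sample with no evidence at all (M parameter missing, no date, no
    diagnosis match) is *excluded*; everything else is *primary*.
    """

    sample_id: str
    m_parameter: int | None = None
    metastasis_date: str | None = None
    diagnosis_text: str | None = None
    label: Label = Label.EXCLUDED


@dataclass
class FeaturePartition:
    """Probe → gene-symbol map plus the TF / mRNA / unmapped classification."""

    probe_to_symbols: dict[str, list[str]]
    feature_class: dict[str, FeatureClass]

    def probes_of(self, cls: FeatureClass) -> list[str]:
        return [p for p, c in self.feature_class.items() if c is cls]

    @property
    def tf_probes(self) -> list[str]:
        return self.probes_of(FeatureClass.TF)

    @property
    def mrna_probes(self) -> list[str]:
        return self.probes_of(FeatureClass.MRNA)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features × samples expression table.

    Returns a float DataFrame indexed by feature ID with sample-ID columns,
    preserving file order on both axes.  Duplicate feature or sample IDs and
    ragged rows are rejected with the offending ID / line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: expected at least one sample column")
        sample_ids = header[1:]
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise ValueError(f"{path}: duplicate sample ID {dup!r}")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            fid = parts[0]
            if fid in seen:
                raise ValueError(f"{path}: duplicate feature ID {fid!r}")
            seen.add(fid)
            feature_ids.append(fid)
            rows.append([_parse_cell(c) for c in parts[1:]])
    values = np.asarray(rows, dtype=float)
    if values.size and np.isinf(values).any():
        raise ValueError(f"{path}: non-finite expression value")
    return pd.DataFrame(values, index=feature_ids, columns=sample_ids)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a features × samples table in the dialect ``read_expression_matrix`` reads.

    Floats are written with :func:`repr` precision so a write/read round trip
    reproduces the matrix exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for fid, row in zip(matrix.index, matrix.to_numpy()):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


def _parse_cell(cell: str) -> float:
    if cell.strip().lower() in _NA_STRINGS:
        return float("nan")
    return float(cell)


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# annotation / registry / metadata readers


def read_platform_annotation(path: str | Path) -> dict[str, list[str]]:
    """Read a probe → gene-symbol annotation table.

    Expects columns ``probe_id`` and ``gene_symbols`` (tab-separated, with a
    header); symbols within a cell are ``///``-delimited.  An empty cell means
    the probe maps to no symbol.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        probe_col, sym_col = cols["probe_id"], cols["gene_symbols"]
    except KeyError as exc:
        raise ValueError(
            f"{path}: annotation needs columns probe_id and gene_symbols"
        ) from exc
    out: dict[str, list[str]] = {}
    for probe, cell in zip(df[probe_col], df[sym_col]):
        if probe in out:
            raise ValueError(f"{path}: duplicate probe ID {probe!r}")
        symbols = [s.strip() for s in cell.split("///") if s.strip()]
        out[probe] = symbols
    return out


def read_tf_registry(path: str | Path) -> set[str]:
    """Read a flat one-symbol-per-line transcription-factor registry."""
    with Path(path).open() as fh:
        return {line.strip() for line in fh if line.strip()}


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, m_parameter, metastasis_date, diagnosis)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id"}
    missing = required - set(c.lower() for c in df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# label curation


def curate_labels(
    records: pd.DataFrame | Iterable[Mapping[str, object]],
    metastasis_keywords: Sequence[str] = DEFAULT_METASTASIS_KEYWORDS,
) -> list[SampleAnnotation]:
    """Derive primary / metastatic / excluded labels from raw metadata.

    The rule: metastatic if the M parameter exceeds 0, a metastasis date is
    present, or the diagnosis text matches a metastasis keyword
    (case-insensitive substring); excluded if the M parameter is missing and
    no other evidence exists; primary otherwise.  Deterministic and
    order-independent: each record is labelled on its own.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    keywords = tuple(k.lower() for k in metastasis_keywords)
    out: list[SampleAnnotation] = []
    seen: set[str] = set()
    for rec in records:
        sid = str(rec["sample_id"])
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        m = _coerce_m(rec.get("m_parameter"))
        date = _coerce_str(rec.get("metastasis_date"))
        diag = _coerce_str(rec.get("diagnosis") or rec.get("diagnosis_text"))
        diag_hit = diag is not None and any(k in diag.lower() for k in keywords)
        if (m is not None and m > 0) or date is not None or diag_hit:
            label = Label.METASTATIC
        elif m is None:
            label = Label.EXCLUDED
        else:
            label = Label.PRIMARY
        out.append(
            SampleAnnotation(
                sample_id=sid,
                m_parameter=m,
                metastasis_date=date,
                diagnosis_text=diag,
                label=label,
            )
        )
    return out


def _coerce_m(value: object) -> int | None:
    s = _coerce_str(value)
    if s is None:
        return None
    m = int(float(s))
    if m < 0:
        raise ValueError(f"negative M parameter {m}")
    return m


def _coerce_str(value: object) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s.lower() in _NA_STRINGS:
        return None
    return s


def split_by_label(
    annotations: Sequence[SampleAnnotation],
) -> tuple[list[str], list[str], list[str]]:
    """Return (primary, metastatic, excluded) sample-ID lists in input order."""
    prim = [a.sample_id for a in annotations if a.label is Label.PRIMARY]
    met = [a.sample_id for a in annotations if a.label is Label.METASTATIC]
    excl = [a.sample_id for a in annotations if a.label is Label.EXCLUDED]
    return prim, met, excl


# ---------------------------------------------------------------------------
# feature partition


def partition_features(
    annotation: Mapping[str, list[str]], registry: set[str]
) -> FeaturePartition:
    """Classify every probe as TF, mRNA or unmapped.

    A probe is a TF feature if *any* of its mapped symbols is in the TF
    registry (a probe partly measuring a TF must not serve as a regression
    target), an mRNA feature if it maps to at least one symbol none of which
    is a TF, and unmapped if it maps to no symbol.
    """
    if not registry:
        raise ValueError("TF registry is empty; nothing can be a predictor")
    classes: dict[str, FeatureClass] = {}
    for probe, symbols in annotation.items():
        if not symbols:
            classes[probe] = FeatureClass.UNMAPPED
        elif any(s in registry for s in symbols):
            classes[probe] = FeatureClass.TF
        else:
            classes[probe] = FeatureClass.MRNA
    return FeaturePartition(probe_to_symbols=dict(annotation), feature_class=classes)
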