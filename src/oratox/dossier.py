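"""Data model for oral-toxicity dossier studies and substances.

A *study* is a single animal test result: an acute oral LD50 (OECD TG
401/420/423/425) or a repeated-dose NOAEL (28-day TG 407, 90-day TG 408),
in mg/kg body weight, together with its reliability metadata (Klimisch
score, key-study flag, read-across flag). A *substance* carries a binary
substructure fingerprint, a vector of molecular descriptors, and GHS oral
hazard flags (H300-H305).

Substance-level endpoint values are the arithmetic mean of the studies that
pass a :class:`SelectionRule` (e.g. "Klimisch 1 acute studies only"); a
substance is labelled an oral toxicant when that mean LD50 is strictly
below 2,000 mg/kg b.w.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ENDPOINTS",
    "GUIDELINES",
    "ACUTE_GUIDELINES",
    "QUALIFIERS",
    "HAZARD_CODES",
    "HAZARD_STATUSES",
    "DESCRIPTOR_NAMES",
    "STUDY_COLUMNS",
    "StudyRecord",
    "SubstanceRecord",
    "AggregatedEndpoint",
    "SelectionRule",
    "SchemaError",
    "RowError",
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "studies_to_frame",
    "frame_to_studies",
    "read_fingerprints",
    "write_fingerprints",
    "read_descriptor_table",
    "write_descriptor_table",
    "aggregate_substance_value",
    "aggregate_dataset",
    "label_toxicant",
]

ENDPOINTS = ("acute_oral", "repeated_28d", "repeated_90d")
GUIDELINES = ("TG401", "TG420", "TG423", "TG425", "TG407", "TG408", "other")
ACUTE_GUIDELINES = ("TG401", "TG420", "TG423", "TG425")
QUALIFIERS = ("exact", "greater_than", "greater_equal")
HAZARD_CODES = ("H300", "H301", "H302", "H303", "H304", "H305")
HAZARD_STATUSES = ("positive", "negative", "data_lacking", "inconclusive")

#: guideline -> the single endpoint it may report ("other" is unrestricted)
GUIDELINE_ENDPOINT = {
    "TG401": "acute_oral",
    "TG420": "acute_oral",
    "TG423": "acute_oral",
    "TG425": "acute_oral",
    "TG407": "repeated_28d",
    "TG408": "repeated_90d",
}

#: The 27 molecular descriptors of the modeling table (KNN excluded).
DESCRIPTOR_NAMES = (
    "TPSA",
    "AcidicGroupCount",
    "Apol",
    "HBondAcceptorCount",
    "RuleOfFive",
    "EccentricConnectivity",
    "MannholdLogP",
    "AromaticAtomsCount",
    "Bpol",
    "ZagrebIndex",
    "FractionalPSA",
    "LargestPiSystem",
    "XLogP",
    "LargestChain",
    "HybridizationRatio",
    "AromaticBondsCount",
    "RotatableBondsCount",
    "AtomCount",
    "FragmentComplexity",
    "Weight",
    "BondCount",
    "VadjMaDescriptor",
    "LongestAliphaticChain",
    "PetitjeanNumber",
    "FMF",
    "HBondDonorCount",
    "BasicGroupCount",
)

STUDY_COLUMNS = (
    "substance_id",
    "endpoint",
    "guideline",
    "klimisch",
    "key_study",
    "read_across",
    "value",
    "qualifier",
)


class SchemaError(ValueError):
    """A table is missing a required column or carries an unknown schema."""


class RowError(ValueError):
    """A single data row violates the study-record invariants."""


class StudyTableError(ValueError):
    """One or more rows of a study table failed validation.

    Attributes
    ----------
    row_errors : list of (row_index, message)
        0-based data-row indices (header excluded) with diagnostics.
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"row {i}: {msg}" for i, msg in row_errors[:10])
        more = "" if len(row_errors) <= 10 else f" (+{len(row_errors) - 10} more)"
        super().__init__(f"{len(row_errors)} invalid study rows: {lines}{more}")


@dataclass(frozen=True)
class StudyRecord:
    """One toxicology study (LD50 for acute, NOAEL for repeated endpoints)."""

    substance_id: str
    endpoint: str
    guideline: str
    klimisch: int
    is_key_study: bool
    is_read_across: bool
    value_mg_per_kg: float
    qualifier: str = "exact"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise RowError(f"unknown endpoint {self.endpoint!r}")
        if self.guideline not in GUIDELINES:
            raise RowError(f"unknown guideline {self.guideline!r}")
        expected = GUIDELINE_ENDPOINT.get(self.guideline)
        if expected is not None and expected != self.endpoint:
            raise RowError(
                f"guideline {self.guideline} reports {expected}, not {self.endpoint}"
            )
        if not 1 <= int(self.klimisch) <= 4:
            raise RowError(f"klimisch score {self.klimisch} outside 1-4")
        if not np.isfinite(self.value_mg_per_kg) or self.value_mg_per_kg <= 0:
            raise RowError(f"non-positive endpoint value {self.value_mg_per_kg}")
        if self.qualifier not in QUALIFIERS:
            raise RowError(f"unknown qualifier {self.qualifier!r}")


@dataclass
class SubstanceRecord:
    """A substance: fingerprint, descriptor vector and GHS hazard flags."""

    substance_id: str
    fingerprint: np.ndarray | None = None
    descriptors: dict[str, float] = field(default_factory=dict)
    hazard_flags: dict[str, str] = field(default_factory=dict)
    module: int | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        for code, status in self.hazard_flags.items():
            if code not in HAZARD_CODES:
                raise ValueError(f"unknown hazard code {code!r}")
            if status not in HAZARD_STATUSES:
                raise ValueError(f"unknown hazard status {status!r}")


@dataclass(frozen=True)
class SelectionRule:
    """Study filter producing a substance-level aggregate.

    ``max_klimisch=1`` restricts to fully reliable studies (the modeling
    dataset convention); ``key_only`` keeps registrant key studies and
    drops read-across.
    """

    max_klimisch: int = 4
    guidelines: tuple[str, ...] | None = None
    key_only: bool = False
    include_read_across: bool = True

    def __call__(self, study: StudyRecord) -> bool:
        if study.klimisch > self.max_klimisch:
            return False
        if self.guidelines is not None and study.guideline not in self.guidelines:
            return False
        if self.key_only and not study.is_key_study:
            return False
        if not self.include_read_across and study.is_read_across:
            return False
        return True


@dataclass(frozen=True)
class AggregatedEndpoint:
    """Substance-level mean endpoint value and the selection that made it."""

    substance_id: str
    endpoint: str
    mean_value: float
    n_studies: int
    selection: SelectionRule

    def __post_init__(self) -> None:
        if self.mean_value <= 0:
            raise ValueError("aggregated endpoint value must be positive")
        if self.n_studies < 1:
            raise ValueError("aggregate requires at least one study")


# ---------------------------------------------------------------------------
# aggregation and labelling


def aggregate_substance_value(
    studies: Sequence[StudyRecord],
    selection: SelectionRule | Callable[[StudyRecord], bool] = SelectionRule(),
    *,
    mean: str = "arithmetic",
) -> AggregatedEndpoint | None:
    """Average one substance's studies under a selection rule.

    Returns ``None`` when no study passes the filter. All studies must
    share a substance id and endpoint. Censored values (qualifier
    ``greater_than``/``greater_equal``) enter the mean at their bound.
    """
    if not studies:
        return None
    ids = {s.substance_id for s in studies}
    if len(ids) != 1:
        raise ValueError(f"mixed substance ids in aggregation: {sorted(ids)}")
    endpoints = {s.endpoint for s in studies}
    if len(endpoints) != 1:
        raise ValueError(f"mixed endpoints in aggregation: {sorted(endpoints)}")
    kept = [s for s in studies if selection(s)]
    if not kept:
        return None
    values = np.array([s.value_mg_per_kg for s in kept], dtype=float)
    if mean == "arithmetic":
        m = float(values.mean())
    elif mean == "geometric":
        m = float(np.exp(np.log(values).mean()))
    else:
        raise ValueError(f"unknown mean kind {mean!r}")
    rule = selection if isinstance(selection, SelectionRule) else SelectionRule()
    return AggregatedEndpoint(
        substance_id=kept[0].substance_id,
        endpoint=kept[0].endpoint,
        mean_value=m,
        n_studies=len(kept),
        selection=rule,
    )


def aggregate_dataset(
    studies: Iterable[StudyRecord],
    selection: SelectionRule = SelectionRule(),
    endpoint: str = "acute_oral",
    *,
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-substance aggregated values for one endpoint.

    Returns a frame indexed by substance_id with columns ``mean_value`` and
    ``n_studies``; substances with no passing study are absent.
    """
    by_substance: dict[str, list[StudyRecord]] = {}
    for s in studies:
        if s.endpoint == endpoint:
            by_substance.setdefault(s.substance_id, []).append(s)
    rows = {}
    for sid, group in by_substance.items():
        agg = aggregate_substance_value(group, selection, mean=mean)
        if agg is not None:
            rows[sid] = (agg.mean_value, agg.n_studies)
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_value", "n_studies"]
    )
    frame.index.name = "substance_id"
    return frame.sort_index()


def label_toxicant(
    agg: AggregatedEndpoint | float, threshold: float = 2000.0
) -> bool:
    """True iff the mean acute LD50 is strictly below ``threshold``.

    A mean of exactly 2,000 mg/kg b.w. is *not* a toxicant (the negative
    class is LD50 >= 2,000).
    """
    if isinstance(agg, AggregatedEndpoint):
        if agg.endpoint != "acute_oral":
            raise ValueError("toxicant label is defined for acute_oral only")
        value = agg.mean_value
    else:
        value = float(agg)
    return value < threshold


# ---------------------------------------------------------------------------
# interchange formats

_QUALIFIER_ALIASES = {
    "": "exact",
    "exact": "exact",
    "=": "exact",
    ">": "greater_than",
    "greater_than": "greater_than",
    ">=": "greater_equal",
    "≥": "greater_equal",
    "greater_equal": "greater_equal",
}

_BOOL_ALIASES = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


def _parse_bool(raw, what: str) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    key = str(raw).strip().lower()
    if key not in _BOOL_ALIASES:
        raise RowError(f"cannot parse {what} flag {raw!r}")
    return _BOOL_ALIASES[key]


def read_study_table(path: str | Path, *, sep: str | None = None) -> list[StudyRecord]:
    """Read a study table (CSV, or TSV for ``.tsv`` files).

    The header must name every column in :data:`STUDY_COLUMNS`. Rows that
    fail validation are collected and reported together in a
    :class:`StudyTableError` carrying 0-based row indices. Row order is
    preserved.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in STUDY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"study table missing columns: {missing}")
    records: list[StudyRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            qualifier = _QUALIFIER_ALIASES.get(str(row.qualifier).strip())
            if qualifier is None:
                raise RowError(f"unknown qualifier {row.qualifier!r}")
            # tolerate a censoring symbol prefixed to the value itself
            raw_value = str(row.value).strip()
            for sym, q in (("≥", "greater_equal"), (">=", "greater_equal"),
                           (">", "greater_than")):
                if raw_value.startswith(sym):
                    raw_value = raw_value[len(sym):].strip()
                    if qualifier == "exact":
                        qualifier = q
                    break
            records.append(
                StudyRecord(
                    substance_id=str(row.substance_id),
                    endpoint=str(row.endpoint),
                    guideline=str(row.guideline),
                    klimisch=int(row.klimisch),
                    is_key_study=_parse_bool(row.key_study, "key_study"),
                    is_read_across=_parse_bool(row.read_across, "read_across"),
                    value_mg_per_kg=float(raw_value),
                    qualifier=qualifier,
                )
            )
        except (RowError, ValueError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise StudyTableError(errors)
    return records


def studies_to_frame(studies: Iterable[StudyRecord]) -> pd.DataFrame:
    rows = [
        {
            "substance_id": s.substance_id,
            "endpoint": s.endpoint,
            "guideline": s.guideline,
            "klimisch": s.klimisch,
            "key_study": s.is_key_study,
            "read_across": s.is_read_across,
            "value": s.value_mg_per_kg,
            "qualifier": s.qualifier,
        }
        for s in studies
    ]
    return pd.DataFrame(rows, columns=list(STUDY_COLUMNS))


def frame_to_studies(frame: pd.DataFrame) -> list[StudyRecord]:
    return [
        StudyRecord(
            substance_id=str(r.substance_id),
            endpoint=str(r.endpoint),
            guideline=str(r.guideline),
            klimisch=int(r.klimisch),
            is_key_study=bool(r.key_study),
            is_read_across=bool(r.read_across),
            value_mg_per_kg=float(r.value),
            qualifier=str(r.qualifier),
        )
        for r in frame.itertuples(index=False)
    ]


def write_study_table(
    studies: Iterable[StudyRecord], path: str | Path, *, sep: str | None = None
) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    studies_to_frame(studies).to_csv(path, sep=sep, index=False)


def write_fingerprints(
    substances: Iterable[SubstanceRecord], path: str | Path
) -> None:
    """Write fingerprints as ``substance_id<TAB>hex`` with a length header."""
    subs = list(substances)
    lengths = {len(s.fingerprint) for s in subs if s.fingerprint is not None}
    if len(lengths) != 1:
        raise ValueError("all fingerprints must be present and share one length")
    n_bits = lengths.pop()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#bits={n_bits}\n")
        for s in subs:
            packed = np.packbits(s.fingerprint)
            fh.write(f"{s.substance_id}\t{packed.tobytes().hex()}\n")


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#bits="):
            raise SchemaError("fingerprint file must begin with '#bits=<n>'")
        n_bits = int(header.split("=", 1)[1])
        out: dict[str, np.ndarray] = {}
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sid, hexed = line.split("\t")
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexed), dtype=np.uint8))
            if len(bits) < n_bits:
                raise SchemaError(f"fingerprint for {sid} shorter than {n_bits} bits")
            if sid in out:
                raise SchemaError(f"duplicate substance id {sid!r}")
            out[sid] = bits[:n_bits].astype(np.uint8)
    return out


def write_descriptor_table(
    substances: Iterable[SubstanceRecord], path: str | Path
) -> None:
    rows = []
    for s in substances:
        row = {"substance_id": s.substance_id}
        row.update({name: s.descriptors[name] for name in DESCRIPTOR_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Descriptor table indexed by substance_id with the 27 named columns."""
    frame = pd.read_csv(path)
    missing = [c for c in ("substance_id", *DESCRIPTOR_NAMES) if c not in frame.columns]
    if missing:
        raise SchemaError(f"descriptor table missing columns: {missing}")
    frame = frame.set_index("substance_id")[list(DESCRIPTOR_NAMES)]
    if frame.isna().any().any():
        raise SchemaError("descriptor table contains missing values")
    return frame
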