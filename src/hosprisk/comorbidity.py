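"""Charlson comorbidity index from ICD-10 diagnosis codes.

The index is a weighted sum over 17 comorbidity groups; a diagnosis code
assigns a patient to a group when a known group prefix is a prefix of the
normalized code (uppercased, dots stripped).  Each group contributes its
weight at most once per admission, and within the two hierarchical pairs
(diabetes with/without chronic complication; metastatic solid tumour vs
any other malignancy) only the more severe member counts.  Unknown codes
are silently ignored (logged at debug level).

The default group → prefix → weight table ships as
``data/charlson_icd10.tsv`` (the standard ICD-10 coding of the index,
weights 1/2/3/6); a replacement table with the same three-column layout
may be supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: (less severe, more severe) pairs where only the more severe counts
HIERARCHY: tuple[tuple[str, str], ...] = (
    ("diabetes_uncomplicated", "diabetes_complicated"),
    ("malignancy", "metastatic_solid_tumour"),
)

CATEGORY_BOUNDS = {
    "zero": (0, 0),
    "mild": (1, 2),
    "moderate": (3, 4),
    "severe": (5, None),
}


@dataclass(frozen=True)
class CharlsonScore:
    """Charlson index value plus its severity category."""

    score: int
    category: str

    def __int__(self) -> int:
        return self.score


def load_mapping(path: str | Path | None = None) -> dict[str, tuple[int, tuple[str, ...]]]:
    """Load a Charlson mapping table: group → (weight, prefixes).

    The table is a 3-column TSV (``group``, ``weight``,
    comma-separated ``prefixes``); prefixes are stored normalized.
    """
    if path is None:
        text = (
            resources.files("hosprisk.data")
            .joinpath("charlson_icd10.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    mapping: dict[str, tuple[int, tuple[str, ...]]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # header row skipped
        group, weight, prefixes = ln.split("\t")
        mapping[group] = (
            int(weight),
            tuple(normalize_code(p) for p in prefixes.split(",")),
        )
    if len(mapping) != 17:
        raise ValueError(
            f"Charlson mapping must define 17 groups, got {len(mapping)}"
        )
    return mapping


_DEFAULT_MAPPING: dict[str, tuple[int, tuple[str, ...]]] | None = None


def default_mapping() -> dict[str, tuple[int, tuple[str, ...]]]:
    global _DEFAULT_MAPPING
    if _DEFAULT_MAPPING is None:
        _DEFAULT_MAPPING = load_mapping()
    return _DEFAULT_MAPPING


def normalize_code(code: str) -> str:
    """Uppercase and strip dots/whitespace from an ICD-10 code."""
    return code.strip().upper().replace(".", "")


def matched_groups(
    icd10_codes: Iterable[str],
    mapping: Mapping[str, tuple[int, tuple[str, ...]]] | None = None,
) -> set[str]:
    """Comorbidity groups matched by any code prefix, after applying the
    hierarchy rules."""
    mapping = mapping or default_mapping()
    groups: set[str] = set()
    for raw in icd10_codes:
        code = normalize_code(str(raw))
        if not code:
            continue
        hit = False
        for group, (_, prefixes) in mapping.items():
            if code.startswith(prefixes):
                groups.add(group)
                hit = True
        if not hit:
            logger.debug("ICD-10 code %r matched no Charlson group", raw)
    for mild, severe in HIERARCHY:
        if severe in groups:
            groups.discard(mild)
    return groups


def charlson_index(
    icd10_codes: Iterable[str],
    mapping: Mapping[str, tuple[int, tuple[str, ...]]] | None = None,
) -> CharlsonScore:
    """Compute the Charlson comorbidity index of one admission.

    Duplicated and unknown codes never change the score; adding a code
    never decreases it.
    """
    mapping = mapping or default_mapping()
    groups = matched_groups(icd10_codes, mapping)
    score = sum(mapping[g][0] for g in groups)
    return CharlsonScore(score, charlson_category(score))


def charlson_category(score: int) -> str:
    """Severity category of a Charlson score: 0 → zero, 1–2 → mild,
    3–4 → moderate, ≥5 → severe."""
    if score < 0:
        raise ValueError(f"Charlson score must be non-negative, got {score}")
    if score == 0:
        return "zero"
    if score <= 2:
        return "mild"
    if score <= 4:
        return "moderate"
    return "severe"
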