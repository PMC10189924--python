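"""Slide identity metadata: barcode parsing, institution aliases, contribution groups.

TCGA-style slide barcodes encode the contributing hospital in a two-character
tissue source site (TSS) field: ``TCGA-<TSS>-<participant>[-...]``.  The TSS
code is unique to an (institution, cancer project) pair, so one institution may
own several codes; grouping and auditing therefore key on the *normalized
institution name*, not the raw code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Manifest columns, in canonical order.
MANIFEST_COLUMNS = ["slide_id", "patient_id", "site_code", "institution", "project"]

_BARCODE_RE = re.compile(r"^(TCGA)-([A-Za-z0-9]{2})-([A-Za-z0-9]+)(?:-.+)?$")


class BarcodeError(ValueError):
    """Raised when a slide identifier does not follow the TCGA barcode pattern."""


@dataclass(frozen=True)
class SlideRecord:
    """One slide's identity within the cohort."""

    slide_id: str
    patient_id: str
    site_code: str
    institution: str
    project: str

    def __post_init__(self) -> None:
        if len(self.site_code) != 2:
            raise ValueError(
                f"site_code must have exactly 2 characters, got {self.site_code!r}"
            )


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of institutions into contribution groups A and B.

    Group A holds institutions contributing strictly more than ``threshold``
    of all slides; everything else is group B.
    """

    groups: Mapping[str, str]
    threshold: float = 0.01

    def group(self, institution: str) -> str:
        return self.groups[institution]

    def members(self, label: str) -> list[str]:
        return sorted(k for k, v in self.groups.items() if v == label)


def parse_barcode(slide_id: str) -> tuple[str, str]:
    """Split a TCGA-style barcode into ``(site_code, patient_id)``.

    The patient identity is the project-site-participant triple
    (``TCGA-XX-NNNN``); trailing sample/portion fields are ignored.

    Raises
    ------
    BarcodeError
        If ``slide_id`` does not match ``TCGA-<TSS>-<participant>[-...]``.
    """
    m = _BARCODE_RE.match(slide_id)
    if m is None:
        raise BarcodeError(f"malformed slide identifier: {slide_id!r}")
    prefix, tss, participant = m.groups()
    return tss, f"{prefix}-{tss}-{participant}"


def default_alias_table() -> dict[str, str]:
    """Alias table shipped with the package (editable TSV, two columns)."""
    text = resources.files("sitebias.data").joinpath("aliases.tsv").read_text()
    return _parse_alias_text(text)


def load_alias_table(path) -> dict[str, str]:
    with open(path) as fh:
        return _parse_alias_text(fh.read())


def _parse_alias_text(text: str) -> dict[str, str]:
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias] = canonical
    return table


def normalize_institution(raw_name: str, alias_table: Mapping[str, str]) -> str:
    """Map an institution name to its canonical form.

    Unknown names pass through unchanged (with a log message); no fuzzy
    matching is attempted — residual naming inconsistencies are a documented
    property of the source metadata and resolving them is the user's call via
    the alias table.
    """
    if raw_name in alias_table:
        return alias_table[raw_name]
    logger.debug("institution %r not in alias table; passed through", raw_name)
    return raw_name


def assign_groups(
    records: pd.DataFrame | Iterable[SlideRecord],
    threshold: float = 0.01,
) -> GroupAssignment:
    """Assign each institution to group A (share > threshold) or B.

    The share is the institution's fraction of all slides; the boundary is
    strict, so an institution at exactly ``threshold`` falls in group B.
    Order of records is irrelevant.
    """
    df = as_manifest(records)
    if len(df) == 0:
        raise ValueError("cannot assign groups on an empty manifest")
    counts = df.groupby("institution")["slide_id"].count()
    n = len(df)
    groups = {inst: ("A" if c / n > threshold else "B") for inst, c in counts.items()}
    return GroupAssignment(groups=groups, threshold=threshold)


def as_manifest(records: pd.DataFrame | Iterable[SlideRecord]) -> pd.DataFrame:
    """Coerce records to a manifest DataFrame with the canonical columns."""
    if isinstance(records, pd.DataFrame):
        missing = set(MANIFEST_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        return records
    return pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "patient_id": r.patient_id,
                "site_code": r.site_code,
                "institution": r.institution,
                "project": r.project,
            }
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return as_manifest(df)


def write_manifest(df: pd.DataFrame, path) -> None:
    as_manifest(df).to_csv(path, sep="\t", index=False)
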