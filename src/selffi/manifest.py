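"""Dataset manifests and positive-pair construction.

A manifest is a CSV with one row per fundus image carrying the linkage the
contrastive objectives exploit: which patient the image belongs to, which eye
(laterality) and which modality it is — ultra-wide-field (UFI) or conventional
(CFI).  Six optional 0/1 label columns annotate the diseases used by the
supervised fine-tuning stage, in the fixed order DM retinopathy, epiretinal
membrane, glaucoma suspect, macular degeneration, retinal break, retinal vein
occlusion.

Three positive-pair strategies are realized by :func:`build_pairs`:

``pair_instance``
    a single image paired with itself; the two contrastive views arise from
    independent augmentation downstream.
``bilateral``
    the left- and right-eye UFI of one patient.
``multimodal``
    the UFI and CFI of the same patient (matched per eye by default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

EYE_SIDES = ("left", "right", "unknown")
MODALITIES = ("UFI", "CFI")
PAIR_TYPES = ("pair_instance", "bilateral", "multimodal")
LABEL_COLUMNS = ("dm", "em", "gs", "md", "rb", "rvo")
DISEASES = (
    "DM retinopathy",
    "epiretinal membrane",
    "glaucoma suspect",
    "macular degeneration",
    "retinal break",
    "retinal vein occlusion",
)

_REQUIRED_COLUMNS = ("image_id", "patient_id", "eye_side", "modality", "path")


class ManifestError(ValueError):
    """Raised for malformed manifests or impossible pairing requests."""


@dataclass(frozen=True)
class ImageRecord:
    """One image with its patient linkage and optional multi-label annotation."""

    image_id: str
    patient_id: str
    eye_side: str
    modality: str
    path: str
    labels: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.eye_side not in EYE_SIDES:
            raise ManifestError(
                f"image {self.image_id!r}: unknown eye_side {self.eye_side!r} "
                f"(expected one of {EYE_SIDES})"
            )
        if self.modality not in MODALITIES:
            raise ManifestError(
                f"image {self.image_id!r}: unknown modality {self.modality!r} "
                f"(expected one of {MODALITIES})"
            )
        if self.labels is not None:
            if len(self.labels) != 6 or any(v not in (0, 1) for v in self.labels):
                raise ManifestError(
                    f"image {self.image_id!r}: labels must be six 0/1 values, "
                    f"got {self.labels!r}"
                )


@dataclass(frozen=True)
class PairExample:
    """A typed positive pair referencing one or two :class:`ImageRecord` s."""

    pair_type: str
    record_a: ImageRecord
    record_b: ImageRecord

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ManifestError(f"unknown pair_type {self.pair_type!r}")
        a, b = self.record_a, self.record_b
        if self.pair_type == "pair_instance":
            if a != b:
                raise ManifestError("pair_instance requires record_a == record_b")
        elif self.pair_type == "bilateral":
            if a.patient_id != b.patient_id:
                raise ManifestError("bilateral pair spans two patients")
            if {a.eye_side, b.eye_side} != {"left", "right"}:
                raise ManifestError("bilateral pair must join a left and a right eye")
            if a.modality != "UFI" or b.modality != "UFI":
                raise ManifestError("bilateral pairing is defined on UFI images")
        else:  # multimodal
            if a.patient_id != b.patient_id:
                raise ManifestError("multimodal pair spans two patients")
            if a.modality == b.modality:
                raise ManifestError("multimodal pair must join two modalities")


def read_manifest(path: str | Path) -> list[ImageRecord]:
    """Parse a manifest CSV into :class:`ImageRecord` s.

    Rows with missing required fields and duplicate ``image_id`` s are hard
    errors that name the offending row(s).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ImageRecord] = []
    seen: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ManifestError(f"manifest {path} lacks required columns: {missing}")
        has_labels = all(c in header for c in LABEL_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            for col in _REQUIRED_COLUMNS:
                if not (row.get(col) or "").strip():
                    raise ManifestError(f"row {lineno}: missing required field {col!r}")
            image_id = row["image_id"].strip()
            if image_id in seen:
                raise ManifestError(
                    f"duplicate image_id {image_id!r} at rows {seen[image_id]} "
                    f"and {lineno}"
                )
            seen[image_id] = lineno
            labels = None
            if has_labels and all((row.get(c) or "").strip() for c in LABEL_COLUMNS):
                try:
                    labels = tuple(int(row[c]) for c in LABEL_COLUMNS)
                except ValueError as exc:
                    raise ManifestError(f"row {lineno}: non-integer label: {exc}")
            records.append(
                ImageRecord(
                    image_id=image_id,
                    patient_id=row["patient_id"].strip(),
                    eye_side=row["eye_side"].strip(),
                    modality=row["modality"].strip(),
                    path=row["path"].strip(),
                    labels=labels,
                )
            )
    return records


def write_manifest(records: Sequence[ImageRecord], path: str | Path) -> Path:
    """Write records back to the manifest CSV dialect (round-trip safe)."""
    path = Path(path)
    with_labels = any(r.labels is not None for r in records)
    header = list(_REQUIRED_COLUMNS) + (list(LABEL_COLUMNS) if with_labels else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [r.image_id, r.patient_id, r.eye_side, r.modality, r.path]
            if with_labels:
                row += list(r.labels) if r.labels is not None else [""] * 6
            writer.writerow(row)
    return path


def _slot_index(records: Sequence[ImageRecord]) -> dict[tuple[str, str, str], ImageRecord]:
    """Map (patient, eye, modality) -> record, resolving duplicates by smallest id."""
    index: dict[tuple[str, str, str], ImageRecord] = {}
    for r in sorted(records, key=lambda r: r.image_id):
        key = (r.patient_id, r.eye_side, r.modality)
        index.setdefault(key, r)
    return index


def build_pairs(
    records: Sequence[ImageRecord],
    strategy: str,
    seed: int = 0,
    *,
    modality: str = "UFI",
    match_multimodal_per_eye: bool = True,
) -> list[PairExample]:
    """Build the positive-pair list for one contrastive objective.

    ``pair_instance`` yields one self-pair per record of ``modality``;
    ``bilateral`` one pair per patient with both a left- and right-eye UFI;
    ``multimodal`` one UFI–CFI pair per (patient, eye) with both modalities,
    or per patient when ``match_multimodal_per_eye`` is off.  Output order is
    shuffled deterministically by ``seed``.
    """
    if not records:
        raise ManifestError("no records to pair")
    if strategy not in PAIR_TYPES:
        raise ManifestError(f"unknown pairing strategy {strategy!r}")
    index = _slot_index(records)
    pairs: list[PairExample] = []
    if strategy == "pair_instance":
        for r in sorted(records, key=lambda r: r.image_id):
            if r.modality == modality:
                pairs.append(PairExample("pair_instance", r, r))
    elif strategy == "bilateral":
        patients = sorted({r.patient_id for r in records if r.eye_side != "unknown"})
        for pid in patients:
            left = index.get((pid, "left", "UFI"))
            right = index.get((pid, "right", "UFI"))
            if left is not None and right is not None:
                pairs.append(PairExample("bilateral", left, right))
    else:  # multimodal
        if match_multimodal_per_eye:
            keys = sorted({(r.patient_id, r.eye_side) for r in records})
            for pid, eye in keys:
                ufi = index.get((pid, eye, "UFI"))
                cfi = index.get((pid, eye, "CFI"))
                if ufi is not None and cfi is not None:
                    pairs.append(PairExample("multimodal", ufi, cfi))
        else:
            by_patient: dict[str, dict[str, ImageRecord]] = {}
            for r in sorted(records, key=lambda r: r.image_id):
                by_patient.setdefault(r.patient_id, {}).setdefault(r.modality, r)
            for pid in sorted(by_patient):
                slots = by_patient[pid]
                if "UFI" in slots and "CFI" in slots:
                    pairs.append(PairExample("multimodal", slots["UFI"], slots["CFI"]))
    if not pairs:
        hints = {
            "pair_instance": f"no records of modality {modality!r}",
            "bilateral": "no patient has both a left- and a right-eye UFI",
            "multimodal": "no patient/eye has both a UFI and a CFI image",
        }
        raise ManifestError(f"{strategy} pairing produced zero pairs: {hints[strategy]}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]
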