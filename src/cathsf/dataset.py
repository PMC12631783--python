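"""Labelled splits and the dataset filter cascade.

Domains carry a CATH superfamily label (e.g. ``3.40.50.720``) and belong
to one of three fixed splits (train/val/test).  Before training, three
optional filters are applied in a fixed order:

1. structure availability — when the classifier input involves the 3Di
   channel, domains whose structure could not be retrieved or mapped are
   dropped (AA-only runs keep them);
2. pLDDT threshold — training domains whose mean pLDDT is *under* the
   threshold are dropped (low-confidence predicted models produce
   low-quality 3Di strings);
3. support threshold — superfamilies whose training support is ≤ the
   threshold are dropped from all splits (classes too small to learn).

After each stage the label space is re-harmonized: a superfamily with no
training domains left is removed from validation and test as well, so the
label space is always exactly the sorted distinct training labels.  Every
removal is counted in the bundle's provenance, stage by stage, so input
counts always reconcile with survivors plus removals.

Boundary semantics: the pLDDT filter removes strictly-below-threshold
domains (threshold 24.0 keeps a domain at exactly 24.0); the support
filter removes at-or-below-threshold superfamilies (threshold 10 removes
a superfamily with train support exactly 10).  Threshold 0 disables
either filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyDatasetError,
    IntegrityError,
)
from .structure_io import AlignmentMapping, StructureModel, extract_mean_plddt

SPLITS = ("train", "val", "test")

PLDDT_THRESHOLD_GRID = (0, 4, 14, 24, 34, 44, 54, 64, 74, 84)
SUPPORT_THRESHOLD_GRID = (0, 10)

__all__ = [
    "SPLITS", "PLDDT_THRESHOLD_GRID", "SUPPORT_THRESHOLD_GRID",
    "DomainRecord", "FilterConfig", "SplitBundle",
    "attach_structure_metadata", "apply_structure_filter",
    "apply_plddt_filter", "apply_support_filter", "harmonize_label_space",
    "apply_filter_cascade", "read_domain_table", "write_domain_table",
]


@dataclass(frozen=True)
class DomainRecord:
    """One domain: sequence, superfamily label, split, structure metadata."""

    domain_id: str
    aa_sequence: str
    sf_label: str
    split: str
    mean_plddt: Optional[float] = None
    structure_available: bool = False

    def __post_init__(self):
        if not self.aa_sequence:
            raise IntegrityError(f"domain {self.domain_id!r}: empty sequence")
        if not self.sf_label:
            raise IntegrityError(f"domain {self.domain_id!r}: empty label")
        if self.split not in SPLITS:
            raise IntegrityError(f"domain {self.domain_id!r}: unknown split "
                                 f"{self.split!r}")
        if self.mean_plddt is not None:
            if not 0.0 <= self.mean_plddt <= 100.0:
                raise IntegrityError(
                    f"domain {self.domain_id!r}: mean pLDDT "
                    f"{self.mean_plddt} outside [0, 100]")
            if not self.structure_available:
                raise IntegrityError(
                    f"domain {self.domain_id!r}: mean pLDDT present but "
                    "structure_available is False")


@dataclass(frozen=True)
class FilterConfig:
    """The dataset filter settings for one run."""

    plddt_threshold: float = 0.0
    support_threshold: int = 0
    require_structure: bool = False

    def __post_init__(self):
        if self.plddt_threshold < 0 or self.support_threshold < 0:
            raise ConfigurationError("filter thresholds must be >= 0")

    def validate_for_input_type(self, input_type: str) -> None:
        """3Di-bearing inputs need structures; AA-only must keep
        structure-less domains (it suffers no superfamily loss)."""
        involves_3di = "3Di" in input_type
        if involves_3di and not self.require_structure:
            raise ConfigurationError(
                f"input_type {input_type!r} involves the 3Di channel; "
                "require_structure must be true")
        if not involves_3di and self.require_structure:
            raise ConfigurationError(
                "require_structure=true is meaningless for AA-only input; "
                "AA-only runs keep structure-less domains")
        if self.plddt_threshold > 0 and not self.require_structure:
            raise ConfigurationError(
                "a pLDDT threshold needs structure metadata; set "
                "require_structure or use a 3Di-bearing input_type")


@dataclass(frozen=True)
class SplitBundle:
    """Train/val/test records plus the harmonized label space.

    ``label_space`` is the sorted distinct training labels; integer class
    indices are assigned in that order.  ``provenance`` accumulates one
    entry per filter stage with the counts removed.
    """

    train: tuple[DomainRecord, ...]
    val: tuple[DomainRecord, ...]
    test: tuple[DomainRecord, ...]
    label_space: tuple[str, ...]
    provenance: tuple[dict, ...] = ()

    def __post_init__(self):
        ids: dict[str, str] = {}
        for split_name in SPLITS:
            for r in getattr(self, split_name):
                if r.split != split_name:
                    raise IntegrityError(
                        f"record {r.domain_id!r} has split {r.split!r} but "
                        f"sits in the {split_name} list")
                if r.domain_id in ids:
                    raise IntegrityError(
                        f"duplicate domain id {r.domain_id!r} across splits "
                        f"({ids[r.domain_id]} and {split_name})")
                ids[r.domain_id] = split_name
        if self.label_space != tuple(sorted({r.sf_label for r in self.train})):
            raise IntegrityError(
                "label_space must be the sorted distinct train labels")

    @classmethod
    def from_records(cls, records: Sequence[DomainRecord]) -> "SplitBundle":
        """Assemble a bundle and harmonize its label space."""
        by_split = {s: tuple(r for r in records if r.split == s)
                    for s in SPLITS}
        bundle = cls(
            train=by_split["train"], val=by_split["val"],
            test=by_split["test"],
            label_space=tuple(sorted({r.sf_label for r in by_split["train"]})),
        )
        return harmonize_label_space(bundle)

    def records(self) -> tuple[DomainRecord, ...]:
        return self.train + self.val + self.test

    def counts(self) -> dict[str, int]:
        return {s: len(getattr(self, s)) for s in SPLITS}

    def class_index(self) -> dict[str, int]:
        """sf_label → integer class index, by label_space order."""
        return {lab: i for i, lab in enumerate(self.label_space)}

    def train_support(self) -> dict[str, int]:
        support: dict[str, int] = {}
        for r in self.train:
            support[r.sf_label] = support.get(r.sf_label, 0) + 1
        return support

    def check_invariants(self) -> None:
        """Label closure: val/test labels are a subset of train labels."""
        train_labels = set(self.label_space)
        stray = {r.sf_label for r in self.val + self.test} - train_labels
        if stray:
            raise IntegrityError(
                f"val/test labels absent from train: {sorted(stray)[:5]}")


def attach_structure_metadata(
    records: Sequence[DomainRecord],
    structures: Mapping[str, Optional[tuple[StructureModel, AlignmentMapping]]],
) -> list[DomainRecord]:
    """Fill per-record structure availability and mean pLDDT.

    ``structures`` maps domain id to a (model, mapping) pair, or to None
    for a planted/observed failure (file not retrievable, mapping below
    thresholds).  Failures are recorded on the record, never fatal.
    Domains absent from the mapping are marked structure-unavailable.
    """
    seen: set[str] = set()
    out: list[DomainRecord] = []
    for r in records:
        if r.domain_id in seen:
            raise IntegrityError(f"duplicate domain id {r.domain_id!r}")
        seen.add(r.domain_id)
        pair = structures.get(r.domain_id)
        if pair is None:
            out.append(replace(r, structure_available=False, mean_plddt=None))
            continue
        model, mapping = pair
        plddt = None
        if model.source_kind == "predicted":
            plddt = extract_mean_plddt(model, mapping)
        out.append(replace(r, structure_available=True, mean_plddt=plddt))
    return out


def _rebuild(bundle: SplitBundle, train, val, test, stage: dict) -> SplitBundle:
    new = SplitBundle(
        train=tuple(train), val=tuple(val), test=tuple(test),
        label_space=tuple(sorted({r.sf_label for r in train})),
        provenance=bundle.provenance + (stage,),
    )
    return new


def apply_structure_filter(bundle: SplitBundle,
                           require_structure: bool) -> SplitBundle:
    """Drop structure-unavailable domains (all splits) when required."""
    if not require_structure:
        stage = {"stage": "structure", "require_structure": False,
                 "removed": {s: 0 for s in SPLITS}, "removed_sfs": 0}
        return _rebuild(bundle, bundle.train, bundle.val, bundle.test, stage)
    kept = {s: [r for r in getattr(bundle, s) if r.structure_available]
            for s in SPLITS}
    stage = {
        "stage": "structure", "require_structure": True,
        "removed": {s: len(getattr(bundle, s)) - len(kept[s]) for s in SPLITS},
    }
    out = _rebuild(bundle, kept["train"], kept["val"], kept["test"], stage)
    stage["removed_sfs"] = len(bundle.label_space) - len(out.label_space)
    return harmonize_label_space(out)


def apply_plddt_filter(bundle: SplitBundle, threshold: float) -> SplitBundle:
    """Drop training domains whose mean pLDDT is under the threshold.

    The criterion applies to training domains only; validation and test
    shrink solely through whole-superfamily removal when a superfamily
    loses its last training domain.  Threshold 0 disables the filter
    (pLDDT is never negative).
    """
    if threshold < 0:
        raise ConfigurationError("pLDDT threshold must be >= 0")
    if threshold == 0:
        stage = {"stage": "plddt", "threshold": 0.0,
                 "removed": {s: 0 for s in SPLITS}, "removed_sfs": 0}
        return _rebuild(bundle, bundle.train, bundle.val, bundle.test, stage)
    missing = [r.domain_id for r in bundle.train if r.mean_plddt is None]
    if missing:
        raise ConfigurationError(
            f"pLDDT threshold {threshold} requires mean pLDDT on every "
            f"training record; {len(missing)} lack it "
            f"(e.g. {missing[:3]}) — run the structure filter first")
    kept_train = [r for r in bundle.train if r.mean_plddt >= threshold]
    stage = {
        "stage": "plddt", "threshold": float(threshold),
        "removed": {"train": len(bundle.train) - len(kept_train),
                    "val": 0, "test": 0},
    }
    out = _rebuild(bundle, kept_train, bundle.val, bundle.test, stage)
    stage["removed_sfs"] = len(bundle.label_space) - len(out.label_space)
    return harmonize_label_space(out)


def apply_support_filter(bundle: SplitBundle, threshold: int) -> SplitBundle:
    """Drop superfamilies with training support ≤ threshold, in all splits.

    Threshold 0 is a no-op (support of an existing superfamily is ≥ 1).
    """
    if threshold < 0:
        raise ConfigurationError("support threshold must be >= 0")
    if threshold == 0:
        stage = {"stage": "support", "threshold": 0,
                 "removed": {s: 0 for s in SPLITS}, "removed_sfs": 0}
        return _rebuild(bundle, bundle.train, bundle.val, bundle.test, stage)
    support = bundle.train_support()
    doomed = {sf for sf, n in support.items() if n <= threshold}
    kept = {s: [r for r in getattr(bundle, s) if r.sf_label not in doomed]
            for s in SPLITS}
    stage = {
        "stage": "support", "threshold": int(threshold),
        "removed": {s: len(getattr(bundle, s)) - len(kept[s]) for s in SPLITS},
        "removed_sfs": len(doomed),
    }
    out = _rebuild(bundle, kept["train"], kept["val"], kept["test"], stage)
    return harmonize_label_space(out)


def harmonize_label_space(bundle: SplitBundle) -> SplitBundle:
    """Drop val/test records whose label has no training domains left."""
    if not bundle.train:
        raise EmptyDatasetError("training set empty after filtering")
    train_labels = set(bundle.label_space)
    kept_val = [r for r in bundle.val if r.sf_label in train_labels]
    kept_test = [r for r in bundle.test if r.sf_label in train_labels]
    n_dropped = (len(bundle.val) - len(kept_val)
                 + len(bundle.test) - len(kept_test))
    if n_dropped == 0 and bundle.provenance and \
            bundle.provenance[-1].get("stage") == "harmonize":
        return bundle
    stage = {
        "stage": "harmonize",
        "removed": {"train": 0,
                    "val": len(bundle.val) - len(kept_val),
                    "test": len(bundle.test) - len(kept_test)},
        "removed_sfs": 0,
    }
    out = _rebuild(bundle, bundle.train, kept_val, kept_test, stage)
    out.check_invariants()
    return out


def apply_filter_cascade(bundle: SplitBundle,
                         config: FilterConfig) -> SplitBundle:
    """Run structure availability → pLDDT → support, then harmonize.

    This order matters: structure loss shrinks class supports before the
    support filter counts them, which mirrors how support counts respond
    to unretrievable structures.
    """
    out = apply_structure_filter(bundle, config.require_structure)
    out = apply_plddt_filter(out, config.plddt_threshold)
    out = apply_support_filter(out, config.support_threshold)
    return harmonize_label_space(out)


_COLUMNS = ["domain_id", "sequence", "sf_label", "split",
            "mean_plddt", "structure_available"]


def read_domain_table(path: str) -> list[DomainRecord]:
    """Read a domain table CSV (columns: domain_id, sequence, sf_label,
    split, mean_plddt, structure_available; the last two optional)."""
    df = pd.read_csv(path, dtype={"domain_id": str, "sf_label": str})
    records = []
    for row in df.itertuples(index=False):
        plddt = getattr(row, "mean_plddt", None)
        if plddt is not None and pd.isna(plddt):
            plddt = None
        avail = bool(getattr(row, "structure_available", plddt is not None))
        records.append(DomainRecord(
            domain_id=str(row.domain_id),
            aa_sequence=str(row.sequence),
            sf_label=str(row.sf_label),
            split=str(row.split),
            mean_plddt=None if plddt is None else float(plddt),
            structure_available=avail,
        ))
    return records


def write_domain_table(records: Sequence[DomainRecord], path: str) -> None:
    df = pd.DataFrame(
        [(r.domain_id, r.aa_sequence, r.sf_label, r.split,
          r.mean_plddt, r.structure_available) for r in records],
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False)
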