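"""Synthetic fixtures with controlled statistical structure.

Two generators cover the pipeline's input surface:

* :func:`gen_structure_set` writes small predicted-model PDB files — a
  helix-like Cα trace per domain (≈3.8 Å consecutive spacing with seeded
  jitter) whose B-factor column realizes a chosen mean pLDDT exactly —
  plus a ground-truth record per domain.  A configurable fraction of
  domains is withheld (no file written) to plant structure-availability
  failures.

* :func:`gen_embedding_dataset` builds a labelled split bundle and
  pooled-embedding stores from a Gaussian-cluster model: each superfamily
  gets one center per channel on a hypersphere of radius ``separation``,
  samples are center + isotropic noise, and selected class *pairs* can be
  collapsed onto a shared center in one channel only — making that
  channel alone insufficient to separate them, which is how per-channel
  informativeness (AA vs 3Di vs both) is controlled.  Per-class training
  supports may follow a power law to emulate the heavy class imbalance of
  real superfamily data, including classes with support below ten.

Both generators are fully seeded: the same spec and seed reproduce
byte-identical files and bit-identical stores.  The Bayes-optimal
accuracy of each channel is computed from the spec (classes sharing a
center in a channel are indistinguishable there, so at most one class
per collapsed group can be predicted correctly) and reported alongside;
the figure assumes ``separation`` is large against ``noise_sd`` so
between-group confusion is negligible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dataset import DomainRecord, SplitBundle
from .embedding import AA_ALPHABET, EmbeddingStore, PooledEmbedding
from .errors import ConfigurationError
from .structure_io import Residue, StructureModel, write_structure

__all__ = [
    "SyntheticSpec", "StructureTruth", "gen_structure_set",
    "gen_embedding_dataset", "nearest_center_predict",
]

_AA20 = AA_ALPHABET[:20]  # no 'X' in generated sequences


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic fixture generators.

    Embedding-dataset fields: ``n_classes``, per-channel dimensions,
    per-class training supports (a constant, an explicit list, or None
    for a power-law profile with ``imbalance_exponent``), cluster
    ``separation`` (hypersphere radius, same units as ``noise_sd``), and
    the per-channel collapsed class pairs.

    Structure-set fields: ``n_domains``, residue-count range, the
    withheld fraction, and the two-component (low/high quality) mean
    pLDDT mixture.
    """

    seed: int = 0
    # --- embedding dataset ---
    n_classes: int = 20
    dim_aa: int = 16
    dim_tdi: int = 16
    train_support: Optional[int | tuple[int, ...]] = None
    imbalance_exponent: float = 1.2
    max_support: int = 60
    n_val_per_class: int = 3
    n_test_per_class: int = 3
    separation: float = 6.0
    noise_sd: float = 1.0
    confusion_aa: tuple[tuple[int, int], ...] = ()
    confusion_tdi: tuple[tuple[int, int], ...] = ()
    # --- structure set ---
    n_domains: int = 10
    n_residues: tuple[int, int] = (30, 60)
    withhold_fraction: float = 0.0
    plddt_low: tuple[float, float] = (55.0, 8.0)   # mean, sd (clipped 20–80)
    plddt_high: tuple[float, float] = (90.0, 3.0)  # mean, sd (clipped 80–97)
    plddt_low_weight: float = 0.4

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_val_per_class < 1 or self.n_test_per_class < 1:
            raise ConfigurationError(
                "need at least one val and one test domain per class")
        for pairs in (self.confusion_aa, self.confusion_tdi):
            for i, j in pairs:
                if not (0 <= i < self.n_classes and 0 <= j < self.n_classes
                        and i != j):
                    raise ConfigurationError(
                        f"invalid collapsed pair ({i}, {j})")
        if not 0.0 <= self.withhold_fraction <= 1.0:
            raise ConfigurationError("withhold_fraction must be in [0, 1]")

    def supports(self) -> np.ndarray:
        """Per-class training supports (power law unless given)."""
        if isinstance(self.train_support, int):
            s = np.full(self.n_classes, self.train_support)
        elif self.train_support is not None:
            s = np.asarray(self.train_support)
            if len(s) != self.n_classes:
                raise ConfigurationError(
                    f"{len(s)} supports for {self.n_classes} classes")
        else:
            ranks = np.arange(1, self.n_classes + 1, dtype=float)
            s = np.maximum(
                1, np.round(self.max_support
                            * ranks ** (-self.imbalance_exponent))
            ).astype(int)
        if (s < 1).any():
            raise ConfigurationError("every class needs train support >= 1")
        return s.astype(int)

    def sf_labels(self) -> list[str]:
        """CATH-style superfamily codes, one per class, unique."""
        return [f"{k % 4 + 1}.{k % 3 * 10 + 10}.{k + 1}.{k * 7 % 90 + 10}"
                for k in range(self.n_classes)]


# ---------------------------------------------------------------------------
# structure set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureTruth:
    """Ground truth for one generated structure."""

    domain_id: str
    sequence: str
    n_residues: int
    mean_plddt: float
    bfactors: tuple[float, ...]
    path: Optional[str]  # None when the file was withheld


def _helix_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    """Idealized α-helical Cα trace: ≈3.8 Å between consecutive residues."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    coords = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i],
                      axis=1)
    return coords + rng.normal(0.0, 0.05, coords.shape)


def gen_structure_set(spec: SyntheticSpec, out_dir: str
                      ) -> list[StructureTruth]:
    """Write predicted-model PDB fixtures and return their ground truth.

    Each domain's B-factor column is noisy around its drawn target mean
    pLDDT and then recentered, so the file's mean pLDDT equals the target
    to float precision.  ``withhold_fraction`` of the domains get no file
    (their ``path`` is None) to plant retrieval failures.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_withheld = int(round(spec.withhold_fraction * spec.n_domains))
    withheld = set(rng.choice(spec.n_domains, size=n_withheld,
                              replace=False).tolist())
    truths: list[StructureTruth] = []
    for d in range(spec.n_domains):
        length = int(rng.integers(spec.n_residues[0], spec.n_residues[1] + 1))
        seq = "".join(rng.choice(list(_AA20), size=length))
        if rng.random() < spec.plddt_low_weight:
            mu, sd = spec.plddt_low
            target = float(np.clip(rng.normal(mu, sd), 20.0, 80.0))
        else:
            mu, sd = spec.plddt_high
            target = float(np.clip(rng.normal(mu, sd), 80.0, 97.0))
        b = rng.normal(0.0, 1.5, length)
        b = target + (b - b.mean())  # exact mean, spread preserved
        coords = _helix_trace(length, rng)
        domain_id = f"syn{spec.seed:02d}_{d:03d}"
        path: Optional[str] = None
        if d not in withheld:
            model = StructureModel(
                structure_id=domain_id, chain_id="A",
                residues=tuple(
                    Residue(seqid=i + 1, icode="", aa_code=seq[i],
                            ca=tuple(coords[i]), bfactor=round(float(b[i]), 2))
                    for i in range(length)),
                source_kind="predicted",
            )
            path = os.path.join(out_dir, f"{domain_id}.pdb")
            write_structure(model, path)
        truths.append(StructureTruth(
            domain_id=domain_id, sequence=seq, n_residues=length,
            mean_plddt=float(np.mean([round(float(x), 2) for x in b])),
            bfactors=tuple(round(float(x), 2) for x in b),
            path=path,
        ))
    return truths


# ---------------------------------------------------------------------------
# embedding dataset
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _collapse_groups(n_classes: int,
                     pairs: tuple[tuple[int, int], ...]) -> list[set[int]]:
    """Connected components of the collapsed-pair graph."""
    parent = list(range(n_classes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for k in range(n_classes):
        groups.setdefault(find(k), set()).add(k)
    return list(groups.values())


def gen_embedding_dataset(spec: SyntheticSpec, store_path: str
                          ) -> tuple[SplitBundle, EmbeddingStore, dict]:
    """Generate a labelled bundle plus AA/3Di pooled-embedding stores.

    Returns ``(bundle, store, info)``; ``info`` carries the per-channel
    class centers and the Bayes-optimal test accuracy per input type
    computed from the collapse structure (classes sharing a center in
    every used channel are indistinguishable; within such a group only
    the group's argmax-prior class can be predicted correctly).
    """
    rng = np.random.default_rng(spec.seed)
    supports = spec.supports()
    labels = spec.sf_labels()
    centers = {
        "AA": np.stack([spec.separation * _unit(rng.standard_normal(spec.dim_aa))
                        for _ in range(spec.n_classes)]),
        "3Di": np.stack([spec.separation * _unit(rng.standard_normal(spec.dim_tdi))
                         for _ in range(spec.n_classes)]),
    }
    for channel, pairs in (("AA", spec.confusion_aa),
                           ("3Di", spec.confusion_tdi)):
        for group in _collapse_groups(spec.n_classes, pairs):
            if len(group) > 1:
                keep = min(group)
                for k in group:
                    centers[channel][k] = centers[channel][keep]

    # deterministic mean pLDDT per domain from the low/high mixture
    records: list[DomainRecord] = []
    store = EmbeddingStore(store_path, mode="w")
    for k in range(spec.n_classes):
        n_total = int(supports[k]) + spec.n_val_per_class + spec.n_test_per_class
        for i in range(n_total):
            if i < supports[k]:
                split = "train"
            elif i < supports[k] + spec.n_val_per_class:
                split = "val"
            else:
                split = "test"
            domain_id = f"C{k:03d}_{i:03d}"
            if rng.random() < spec.plddt_low_weight:
                mu, sd = spec.plddt_low
                plddt = float(np.clip(rng.normal(mu, sd), 20.0, 80.0))
            else:
                mu, sd = spec.plddt_high
                plddt = float(np.clip(rng.normal(mu, sd), 80.0, 97.0))
            seq_len = int(rng.integers(30, 61))
            records.append(DomainRecord(
                domain_id=domain_id,
                aa_sequence="".join(rng.choice(list(_AA20), size=seq_len)),
                sf_label=labels[k], split=split,
                mean_plddt=plddt, structure_available=True,
            ))
            for channel, dim, eid in (("AA", spec.dim_aa, "synthetic-aa"),
                                      ("3Di", spec.dim_tdi, "synthetic-3di")):
                vec = centers[channel][k] + rng.normal(0.0, spec.noise_sd, dim)
                store.put(PooledEmbedding(domain_id=domain_id, vector=vec,
                                          channel=channel,
                                          embedder_ids=(eid,)))
    bundle = SplitBundle.from_records(records)

    # Bayes accuracy per input type from the collapse structure, assuming
    # separation >> noise (between-group overlap negligible)
    test_counts = np.full(spec.n_classes, spec.n_test_per_class, dtype=float)
    # centers rows follow generator class order; class_labels maps row k
    # to its superfamily code (the bundle's label space is sorted, so the
    # two orders differ in general)
    info = {"centers": centers, "supports": supports,
            "class_labels": list(labels), "bayes_accuracy": {}}
    groupings = {
        "AA": _collapse_groups(spec.n_classes, spec.confusion_aa),
        "3Di": _collapse_groups(spec.n_classes, spec.confusion_tdi),
    }
    # AA+3Di: indistinguishable only if collapsed together in BOTH channels
    both: list[set[int]] = []
    for g_aa in groupings["AA"]:
        for g_tdi in groupings["3Di"]:
            inter = g_aa & g_tdi
            if inter:
                both.append(inter)
    groupings["AA+3Di"] = both
    for input_type, groups in groupings.items():
        correct = sum(max(test_counts[k] for k in g) for g in groups)
        info["bayes_accuracy"][input_type] = float(correct / test_counts.sum())
    return bundle, store, info


def nearest_center_predict(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Oracle classifier: assign each row to its nearest class center.

    With isotropic equal-covariance Gaussian classes and equal priors
    this is the Bayes rule; it is used to verify that the reported Bayes
    accuracy is actually approached on large samples.
    """
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)
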