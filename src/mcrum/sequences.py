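"""Small-ncRNA sequence handling: FASTA I/O, fragment sampling, k-mer features.

Mature miRNAs (~15-33 nt) and piRNAs (~16-40 nt) lack strong secondary
structure, so sequences are represented purely by composition: per-k
normalized k-mer frequencies for k = 1..5, concatenated into a
4 + 16 + 64 + 256 + 1024 = 1364-dimensional vector.  Longer background
("other ncRNA") sequences are reduced to a random 20-nt fragment so that
every instance looks like a short sequencing read that could plausibly be a
miRNA or piRNA.

Redundancy reduction of real datasets (e.g. CD-HIT at 80% identity) is a
recommended preprocessing step but is outside this package.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import product

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHABET",
    "KMER_DIM",
    "NcRnaRecord",
    "read_fasta",
    "write_fasta",
    "sample_fragment",
    "kmer_feature_vector",
    "kmer_feature_names",
    "featurize_dataset",
]

ALPHABET = "ACGU"  # lexicographic block order A < C < G < U
_VALID = set(ALPHABET) | {"N"}
KMER_DIM = sum(4**k for k in range(1, 6))  # 1364


@dataclass
class NcRnaRecord:
    """One canonicalized RNA sequence: uppercase, T mapped to U."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")
        self.sequence = seq

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[NcRnaRecord]:
    """Read and canonicalize a FASTA file.

    Records containing characters outside {A, C, G, U, T, N} (after case
    folding) are skipped with a logged warning.  All-N records are retained
    but will fail featurization.
    """
    records: list[NcRnaRecord] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        try:
            records.append(NcRnaRecord(rec.id, str(rec.seq)))
        except ValueError as exc:
            logger.warning("skipping record: %s", exc)
    if n_seen == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if not records:
        raise ValueError(f"no parseable records in {path}")
    return records


def write_fasta(records: list[NcRnaRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def _record_rng(seed: int, record_id: str) -> np.random.Generator:
    # fragment choice depends on the run seed and the record identity only,
    # so it is stable under reordering of the input file
    return np.random.default_rng([seed, zlib.crc32(record_id.encode())])


def sample_fragment(record: NcRnaRecord, length: int = 20, seed: int = 0) -> NcRnaRecord:
    """Uniform random contiguous fragment of ``length`` nt.

    Sequences no longer than ``length`` are returned unchanged.
    Deterministic given the seed and the record id.
    """
    if length < 1:
        raise ValueError("fragment length must be positive")
    if record.length <= length:
        return record
    start = int(_record_rng(seed, record.id).integers(0, record.length - length + 1))
    return NcRnaRecord(record.id, record.sequence[start : start + length])


def kmer_feature_names(k_max: int = 5) -> list[str]:
    return [
        "".join(m) for k in range(1, k_max + 1) for m in product(ALPHABET, repeat=k)
    ]


def kmer_feature_vector(record: NcRnaRecord, k_max: int = 5) -> np.ndarray:
    """Concatenated per-k normalized k-mer frequencies (k = 1..k_max).

    For each k, all length-k windows are scanned; windows containing N are
    skipped and the counts are normalized by the number of windows actually
    counted, so each populated block sums to one.  A block with no valid
    window is all zeros; if even the 1-mer block is empty the sequence is
    uninformative and an error is raised.
    """
    seq = record.sequence
    blocks: list[np.ndarray] = []
    for k in range(1, k_max + 1):
        index = {"".join(m): j for j, m in enumerate(product(ALPHABET, repeat=k))}
        counts = np.zeros(4**k)
        valid = 0
        for s in range(len(seq) - k + 1):
            window = seq[s : s + k]
            j = index.get(window)
            if j is not None:
                counts[j] += 1
                valid += 1
        if k == 1 and valid == 0:
            raise ValueError(
                f"record {record.id!r}: no unambiguous nucleotides to featurize"
            )
        blocks.append(counts / valid if valid else counts)
    return np.concatenate(blocks)


def featurize_dataset(
    records: list[NcRnaRecord],
    labels: list[str],
    fragment_length: int = 20,
    seed: int = 0,
    fragment_class: str | None = None,
    balance: bool = False,
    class_names: list[str] | None = None,
    k_max: int = 5,
) -> LabeledDataset:
    """k-mer feature table for a labeled sequence collection.

    ``fragment_class`` names the background class whose sequences longer than
    ``fragment_length`` are replaced by a random fragment (miRNA/piRNA-sized
    sequences are used whole).  ``balance`` downsamples every class to the
    minority count, seeded, to form a 1:1:...:1 training set.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must align")
    labels = [str(l) for l in labels]
    keep = list(range(len(records)))
    if balance:
        rng = np.random.default_rng(seed)
        by_class: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            by_class.setdefault(lab, []).append(i)
        n_min = min(len(v) for v in by_class.values())
        keep = sorted(
            j
            for idxs in by_class.values()
            for j in rng.choice(idxs, size=n_min, replace=False)
        )
    feats = []
    kept_labels = []
    for i in keep:
        rec = records[i]
        if fragment_class is not None and labels[i] == fragment_class:
            rec = sample_fragment(rec, length=fragment_length, seed=seed)
        feats.append(kmer_feature_vector(rec, k_max=k_max))
        kept_labels.append(labels[i])
    if not feats:
        raise ValueError("no records left to featurize")
    ds = LabeledDataset(np.vstack(feats), kept_labels, class_names=class_names)
    for c in ds.class_names:
        if c not in set(kept_labels):
            raise ValueError(f"class {c!r} is empty after filtering")
    return ds
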