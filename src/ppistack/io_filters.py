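"""File I/O and dataset construction rules.

Reads FASTA sequences (via Biopython), tab-separated pair lists and
localization annotations, and builds the supervised dataset: a positive set
filtered by sequence length (and optionally by pairwise sequence identity),
and a negative set sampled among protein pairs with differing subcellular
localizations, at a fixed ratio to the positives.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .records import PairDataset, ProteinCollection, ProteinRecord, canonical_pair

# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path) -> ProteinCollection:
    """Read a FASTA file into an id-unique, order-preserving collection.

    Sequences are uppercased.  Empty sequences and duplicate identifiers
    raise, naming the offending record.
    """
    path = Path(path)
    records = ProteinCollection()
    for i, entry in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise ValueError(f"{path}: FASTA entry {i} has an empty header")
        if not seq:
            raise ValueError(
                f"{path}: FASTA entry {i} ({entry.id!r}) has an empty sequence"
            )
        try:
            records.add(ProteinRecord(entry.id, seq))
        except ValueError as exc:
            raise ValueError(f"{path}: FASTA entry {i}: {exc}") from exc
    return records


def write_fasta(records: ProteinCollection, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_pairs_tsv(path) -> PairDataset:
    """Read a pair list: TSV with columns idA, idB, label (header optional)."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:3] == ["idA", "idB", "label"]:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(fields)}")
            try:
                label = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: label must be 0/1") from exc
            pairs.append((fields[0], fields[1], label))
    return PairDataset(pairs, provenance=str(path))


def write_pairs_tsv(dataset: PairDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("idA\tidB\tlabel\n")
        for a, b, y in dataset:
            fh.write(f"{a}\t{b}\t{y}\n")


def read_localization_tsv(path) -> dict[str, str]:
    """Read an annotation table: TSV with columns id, localization."""
    table = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:2] == ["id", "localization"]:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            table[fields[0]] = fields[1]
    return table


def write_localization_tsv(table: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlocalization\n")
        for pid, loc in table.items():
            fh.write(f"{pid}\t{loc}\n")


# ---------------------------------------------------------------------------
# positive-set filtering


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global (Needleman-Wunsch) sequence identity: matches / alignment length."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    length = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        sub_a = seq_a[a0:a1]
        sub_b = seq_b[b0:b1]
        matches += sum(x == y for x, y in zip(sub_a, sub_b))
        length += a1 - a0
    # gapped columns count toward alignment length
    aln_len = max(len(str(aln[0])), length)
    return matches / aln_len if aln_len else 0.0


def filter_positive_set(
    records: ProteinCollection,
    pairs: PairDataset,
    min_len: int = 50,
    max_identity: float | None = None,
) -> PairDataset:
    """Apply the positive-set cleaning rules.

    Pairs where either protein is shorter than `min_len` residues are
    removed.  If `max_identity` is given, proteins whose global pairwise
    identity to an already-retained protein exceeds it are dropped (greedy,
    first-seen representative kept) and their pairs removed with them.  The
    identity filter is off by default because the redundancy tool behind the
    published threshold is not specified.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_identity is not None and not 0 < max_identity <= 1:
        raise ValueError("max_identity must be in (0, 1]")
    pairs.validate_against(records)

    kept_ids = [pid for pid in records.ids() if len(records[pid]) >= min_len]

    if max_identity is not None:
        representatives: list[str] = []
        surviving = []
        for pid in kept_ids:
            seq = records[pid].seq
            if any(
                global_identity(seq, records[r].seq) > max_identity
                for r in representatives
            ):
                continue
            representatives.append(pid)
            surviving.append(pid)
        kept_ids = surviving

    kept = set(kept_ids)
    out = [(a, b, y) for a, b, y in pairs if a in kept and b in kept]
    return PairDataset(out, provenance=f"{pairs.provenance} [filtered]")


# ---------------------------------------------------------------------------
# negative sampling


def sample_negatives(
    records: ProteinCollection,
    positives: PairDataset,
    ratio: float = 1.0,
    per_protein_cap: int | None = None,
    rng_seed: int = 0,
) -> PairDataset:
    """Sample non-interacting pairs by differing subcellular localization.

    Draws round(ratio * |positives|) unordered pairs such that the two
    proteins' localizations differ, no sampled pair occurs in the positive
    set, and no protein appears more than `per_protein_cap` times (default
    ceil(2 * n_negatives / n_proteins), which balances per-protein
    contributions without forbidding reuse).  Deterministic for a fixed
    seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    prots = [r for r in records]
    missing = [r.id for r in prots if r.localization is None]
    if missing:
        raise ValueError(
            f"{len(missing)} proteins lack localization labels "
            f"(e.g. {missing[:3]}); attach an annotation table first"
        )
    n_neg = round(ratio * len(positives))
    auto_cap = per_protein_cap is None
    if auto_cap:
        per_protein_cap = math.ceil(2 * n_neg / max(len(prots), 1))
    pos_keys = positives.pair_keys()

    candidates = [
        canonical_pair(a.id, b.id)
        for i, a in enumerate(prots)
        for b in prots[i + 1 :]
        if a.localization != b.localization
        and canonical_pair(a.id, b.id) not in pos_keys
    ]
    if len(candidates) < n_neg:
        raise ValueError(
            f"requested {n_neg} negatives but only {len(candidates)} "
            f"cross-localization non-positive pairs exist"
        )

    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(candidates))
    used: dict[str, int] = {}
    chosen: list[tuple[str, str, int]] = []
    taken: set[int] = set()
    while len(chosen) < n_neg:
        for idx in order:
            if idx in taken:
                continue
            a, b = candidates[idx]
            if used.get(a, 0) >= per_protein_cap or used.get(b, 0) >= per_protein_cap:
                continue
            chosen.append((a, b, 0))
            taken.add(idx)
            used[a] = used.get(a, 0) + 1
            used[b] = used.get(b, 0) + 1
            if len(chosen) == n_neg:
                break
        else:
            if not auto_cap:
                raise ValueError(
                    f"requested {n_neg} negatives but only {len(chosen)} "
                    f"achievable under per_protein_cap={per_protein_cap}"
                )
            # an automatically chosen cap is a balance preference, not a hard
            # constraint: relax it minimally and keep going
            per_protein_cap += 1
    return PairDataset(chosen, provenance=f"negatives(seed={rng_seed})")
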