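"""Data cleaning, subsampling, and leakage-safe splits.

Cleaning mirrors the curation applied to the quantum-chemistry tables: keep
only reaction-solvent pairs present in both the forward and reverse
direction, then drop pairs whose targets exceed magnitude cutoffs (40/56
kcal/mol for the broad pre-training table, 10/18 for the fine-tuning one;
the boundary itself is kept, the inequality is strict).

Splits group by a direction-agnostic reaction key (or by canonical solvent),
so a reaction can never sit in the training set while its reverse sits in
the test set.  All sampling is a pure function of (input, parameters, seed).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from rdkit import Chem

from .errors import UsageError
from .pairtable import PairRecord, group_by
from .reactions import _mol_from_smiles

__all__ = [
    "FilterReport",
    "require_both_directions",
    "filter_outliers",
    "coverage_sample",
    "weighted_solvent_sample",
    "default_solvent_weight",
    "SplitAssignment",
    "make_reaction_split",
    "make_solvent_split",
    "make_random_split",
    "make_folds",
    "write_split_manifest",
]

# cutoffs used for the two curation passes, kcal/mol
PRETRAIN_CUTS = (40.0, 56.0)
FINETUNE_CUTS = (10.0, 18.0)


@dataclass
class FilterReport:
    """Bookkeeping of one filtering pass: kept + sum(removed) = input size."""

    kept: int = 0
    removed: Dict[str, int] = field(default_factory=dict)
    offending: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def note(self, rule: str, record_id: Optional[str]) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + 1
        self.offending.setdefault(rule, []).append(record_id or "?")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"kept": self.kept, "removed": self.removed,
                 "offending": self.offending},
                fh, indent=2,
            )


def _swap_key(directed: str) -> str:
    left, right = directed.split(">>")
    return f"{right}>>{left}"


def require_both_directions(
    records: Sequence[PairRecord],
) -> Tuple[List[PairRecord], FilterReport]:
    """Keep only records whose reaction has both a forward and a reverse
    record *for the same solvent*.  A palindromic reaction (both sides
    canonically identical) counts as its own reverse."""
    directed_by_group: Dict[Tuple[str, str], set] = {}
    directed = [rec.directed_key for rec in records]
    for rec, dk in zip(records, directed):
        directed_by_group.setdefault((rec.reaction_key, rec.solvent_key), set()).add(dk)
    kept: List[PairRecord] = []
    report = FilterReport()
    for rec, dk in zip(records, directed):
        group = directed_by_group[(rec.reaction_key, rec.solvent_key)]
        if _swap_key(dk) in group:
            kept.append(rec)
        else:
            report.note("missing_direction", rec.record_id)
    report.kept = len(kept)
    return kept, report


def filter_outliers(
    records: Sequence[PairRecord], g_cut: float, h_cut: float
) -> Tuple[List[PairRecord], FilterReport]:
    """Drop records with |ddG298| > g_cut or |ddH298| > h_cut (strictly);
    boundary values are kept.  Idempotent."""
    if g_cut <= 0 or h_cut <= 0:
        raise UsageError("cutoffs must be positive")
    kept: List[PairRecord] = []
    report = FilterReport()
    for rec in records:
        if abs(rec.ddG298) > g_cut:
            report.note("g_cutoff", rec.record_id)
        elif abs(rec.ddH298) > h_cut:
            report.note("h_cutoff", rec.record_id)
        else:
            kept.append(rec)
    report.kept = len(kept)
    return kept, report


def default_solvent_weight(smiles: str) -> float:
    """Polarity-proxy sampling weight: 1 + 2·(heteroatoms / heavy atoms)."""
    mol = _mol_from_smiles(smiles)
    mol = Chem.RemoveHs(mol)
    heavy = mol.GetNumAtoms()
    hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    return 1.0 + 2.0 * hetero / max(1, heavy)


def coverage_sample(
    records: Sequence[PairRecord], n: int, seed: int
) -> List[PairRecord]:
    """Semi-random subset of size n in which every reaction key and every
    solvent occurs at least once, when that is feasible.

    A first pass picks one record per uncovered reaction key, then one per
    uncovered solvent (uniformly among candidates); the remainder is filled
    uniformly without replacement.  When n is smaller than the number of
    unique reaction keys the coverage guarantee is impossible and plain
    uniform sampling is used instead.
    """
    if n > len(records):
        raise UsageError(f"cannot sample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    by_reaction = group_by(records, "reaction_key")
    if n < len(by_reaction):
        idx = rng.choice(len(records), size=n, replace=False)
        return [records[i] for i in sorted(idx)]

    chosen: set = set()
    for key in sorted(by_reaction):
        chosen.add(int(rng.choice(by_reaction[key])))
    by_solvent = group_by(records, "solvent_key")
    covered = {records[i].solvent_key for i in chosen}
    for skey in sorted(by_solvent):
        if skey not in covered:
            chosen.add(int(rng.choice(by_solvent[skey])))
    if len(chosen) > n:
        keep = rng.choice(sorted(chosen), size=n, replace=False)
        chosen = set(int(i) for i in keep)
    remaining = [i for i in range(len(records)) if i not in chosen]
    fill = n - len(chosen)
    if fill:
        extra = rng.choice(remaining, size=fill, replace=False)
        chosen.update(int(i) for i in extra)
    return [records[i] for i in sorted(chosen)]


def weighted_solvent_sample(
    records: Sequence[PairRecord],
    per_reaction: int = 25,
    weights: Optional[Union[Dict[str, float], Callable[[str], float]]] = None,
    seed: int = 0,
) -> List[PairRecord]:
    """For each reaction, draw up to ``per_reaction`` distinct solvents
    without replacement with probability proportional to a polarity weight;
    a post-pass swap then guarantees every solvent appears at least once
    globally."""
    rng = np.random.default_rng(seed)

    def weight_of(rec: PairRecord) -> float:
        if weights is None:
            w = default_solvent_weight(rec.solvent)
        elif callable(weights):
            w = weights(rec.solvent)
        else:
            w = weights.get(rec.solvent_key, weights.get(rec.solvent, 1.0))
        if w <= 0:
            raise UsageError(f"nonpositive sampling weight for {rec.solvent!r}")
        return float(w)

    by_reaction = group_by(records, "reaction_key")
    solvents_of: Dict[str, List[str]] = {}
    chosen_groups: Dict[str, set] = {}
    for key in sorted(by_reaction):
        pool = sorted({records[i].solvent_key for i in by_reaction[key]})
        solvents_of[key] = pool
        first = {records[i].solvent_key: i for i in reversed(by_reaction[key])}
        k = min(per_reaction, len(pool))
        w = np.array([weight_of(records[first[s]]) for s in pool])
        picked = rng.choice(len(pool), size=k, replace=False, p=w / w.sum())
        chosen_groups[key] = {pool[j] for j in picked}

    # post-pass: cover solvents that did not make it into any reaction's draw
    counts: Dict[str, int] = {}
    for sel in chosen_groups.values():
        for s in sel:
            counts[s] = counts.get(s, 0) + 1
    all_solvents = sorted({records[i].solvent_key for i in range(len(records))})
    for skey in all_solvents:
        if counts.get(skey, 0) > 0:
            continue
        hosts = sorted(k for k, pool in solvents_of.items() if skey in pool)
        host = hosts[int(rng.integers(len(hosts)))]
        removable = sorted(s for s in chosen_groups[host] if counts.get(s, 0) > 1)
        if removable:
            out = removable[int(rng.integers(len(removable)))]
            chosen_groups[host].discard(out)
            counts[out] -= 1
        chosen_groups[host].add(skey)
        counts[skey] = 1
    return [
        rec for rec in records
        if rec.solvent_key in chosen_groups[rec.reaction_key]
    ]


@dataclass
class SplitAssignment:
    """Per-record role labels for one fold; roles partition the record set."""

    roles: np.ndarray  # (n_records,) of {"train", "val", "test"}
    fold: int = 0
    mode: str = "reaction"
    seed: int = 0

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    @property
    def n_records(self) -> int:
        return self.roles.shape[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _grouped_split(
    records: Sequence[PairRecord],
    group_key: str,
    mode: str,
    test_frac: float,
    val_frac: float,
    seed: int,
    fold: int,
) -> SplitAssignment:
    groups = group_by(records, group_key)
    keys = sorted(groups)
    if len(keys) < 2:
        raise UsageError(f"need at least 2 {mode} groups to split, got {len(keys)}")
    n_test = max(1, _round_half_up(test_frac * len(keys)))
    if n_test >= len(keys):
        raise UsageError(
            f"test fraction {test_frac} selects all {len(keys)} {mode} groups"
        )
    rng = np.random.default_rng(seed)
    test_keys = set(rng.choice(keys, size=n_test, replace=False))
    roles = np.empty(len(records), dtype="<U5")
    rest: List[int] = []
    for i, rec in enumerate(records):
        if getattr(rec, group_key) in test_keys:
            roles[i] = "test"
        else:
            rest.append(i)
    if not rest:
        raise UsageError("test groups swallowed every record")
    rest = np.array(rest)
    rng.shuffle(rest)
    n_val = _round_half_up(val_frac * rest.size)
    roles[rest[:n_val]] = "val"
    roles[rest[n_val:]] = "train"
    return SplitAssignment(roles=roles, fold=fold, mode=mode, seed=seed)


def make_reaction_split(
    records: Sequence[PairRecord],
    test_frac: float = 0.05,
    val_frac: float = 0.2,
    seed: int = 0,
    fold: int = 0,
) -> SplitAssignment:
    """Reaction split: a fraction of direction-agnostic reaction keys goes to
    test with *all* of their records (both directions, every solvent), so a
    forward reaction in train with its reverse in test is impossible; the
    remainder is split 80/20 into train/validation at the record level."""
    return _grouped_split(records, "reaction_key", "reaction", test_frac, val_frac, seed, fold)


def make_solvent_split(
    records: Sequence[PairRecord],
    test_frac: float = 0.05,
    val_frac: float = 0.2,
    seed: int = 0,
    fold: int = 0,
) -> SplitAssignment:
    """Solvent split: grouping key is the canonical solvent."""
    return _grouped_split(records, "solvent_key", "solvent", test_frac, val_frac, seed, fold)


def make_random_split(
    records: Sequence[PairRecord],
    test_frac: float = 0.0,
    val_frac: float = 0.2,
    seed: int = 0,
    fold: int = 0,
) -> SplitAssignment:
    """Plain record-level random split (used for fine-tuning, where the
    holdout is an external set and test_frac is usually zero)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = _round_half_up(test_frac * len(records))
    n_val = _round_half_up(val_frac * (len(records) - n_test))
    roles = np.empty(len(records), dtype="<U5")
    roles[order[:n_test]] = "test"
    roles[order[n_test:n_test + n_val]] = "val"
    roles[order[n_test + n_val:]] = "train"
    if not (roles == "train").any() or not (roles == "val").any():
        raise UsageError("random split produced an empty train or val set")
    return SplitAssignment(roles=roles, fold=fold, mode="random", seed=seed)


def make_folds(
    records: Sequence[PairRecord],
    k: int = 5,
    mode: str = "reaction",
    test_frac: float = 0.05,
    val_frac: float = 0.2,
    seed: int = 0,
) -> List[SplitAssignment]:
    """k independent split redraws with seeds seed..seed+k-1 (each fold is a
    fresh draw, not a partition of a single shuffling)."""
    if k < 1:
        raise UsageError("k must be >= 1")
    maker = {
        "reaction": make_reaction_split,
        "solvent": make_solvent_split,
        "random": make_random_split,
    }.get(mode)
    if maker is None:
        raise UsageError(f"unknown split mode {mode!r}")
    return [
        maker(records, test_frac=test_frac, val_frac=val_frac, seed=seed + f, fold=f)
        for f in range(k)
    ]


def write_split_manifest(
    assignment: SplitAssignment, records: Sequence[PairRecord], path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "fold", "role", "mode", "seed"])
        for rec, role in zip(records, assignment.roles):
            writer.writerow(
                [rec.record_id, assignment.fold, role, assignment.mode, assignment.seed]
            )
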