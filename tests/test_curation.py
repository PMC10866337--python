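"""Cleaning rules, semi-random sampling, and leakage-safe splits."""

import numpy as np
import pytest

from kinsolv.curation import (
    coverage_sample,
    default_solvent_weight,
    filter_outliers,
    make_folds,
    make_reaction_split,
    make_solvent_split,
    require_both_directions,
    weighted_solvent_sample,
    write_split_manifest,
)
from kinsolv.errors import UsageError
from kinsolv.reactions import reverse_reaction
from kinsolv.synthetic import fixture_dataset, generate_reactions

from conftest import H_ABSTRACTION, make_record


def directed_pair(solvent, **kw):
    fwd = make_record(H_ABSTRACTION, solvent, 1.0, 1.0, **kw)
    rev_rxn = reverse_reaction(fwd.reaction)
    from kinsolv.pairtable import PairRecord

    rev = PairRecord(reaction=rev_rxn, solvent=solvent, ddG298=-1.0, ddH298=-1.0)
    return fwd, rev


class TestBothDirections:
    def test_paired_records_kept(self):
        fwd, rev = directed_pair("O")
        kept, report = require_both_directions([fwd, rev])
        assert len(kept) == 2 and report.total_removed == 0

    def test_lone_forward_removed(self):
        fwd, _ = directed_pair("O")
        kept, report = require_both_directions([fwd])
        assert kept == [] and report.removed == {"missing_direction": 1}

    def test_solvent_must_match(self):
        fwd, _ = directed_pair("O")
        _, rev_other = directed_pair("CC")
        kept, report = require_both_directions([fwd, rev_other])
        assert kept == [] and report.total_removed == 2

    def test_every_kept_pair_has_both_orientations(self, small_dataset):
        # drop a third of the records, then re-filter
        subset = [r for i, r in enumerate(small_dataset) if i % 3 != 0]
        kept, _ = require_both_directions(subset)
        groups = {}
        for rec in kept:
            groups.setdefault((rec.reaction_key, rec.solvent_key), set()).add(
                rec.directed_key
            )
        for dks in groups.values():
            assert len(dks) in (1, 2)  # 1 only for palindromic reactions
            for dk in dks:
                left, right = dk.split(">>")
                assert f"{right}>>{left}" in dks

    def test_report_counts_balance(self, small_dataset):
        subset = small_dataset[: len(small_dataset) // 2 + 3]
        kept, report = require_both_directions(subset)
        assert len(kept) + report.total_removed == len(subset)


class TestOutlierFilter:
    def test_strict_inequality_keeps_boundary(self):
        keep = make_record(H_ABSTRACTION, "O", 40.0, 0.0)
        drop = make_record(H_ABSTRACTION, "O", 41.0, 0.0)
        just_over = make_record(H_ABSTRACTION, "O", 40.000001, 0.0)
        kept, report = filter_outliers([keep, drop, just_over], 40.0, 56.0)
        assert kept == [keep]
        assert report.removed == {"g_cutoff": 2}

    def test_finetune_cuts(self):
        rec = make_record(H_ABSTRACTION, "O", 9.0, 19.0)
        kept, report = filter_outliers([rec], 10.0, 18.0)
        assert kept == [] and report.removed == {"h_cutoff": 1}

    def test_empty_input(self):
        kept, report = filter_outliers([], 40.0, 56.0)
        assert kept == [] and report.kept == 0 and report.total_removed == 0

    def test_idempotent(self, small_dataset):
        once, _ = filter_outliers(small_dataset, 3.0, 5.0)
        twice, report = filter_outliers(once, 3.0, 5.0)
        assert twice == once and report.total_removed == 0

    def test_nonpositive_cut_rejected(self):
        with pytest.raises(UsageError):
            filter_outliers([], -1.0, 1.0)


class TestCoverageSample:
    def test_covers_reactions_and_solvents(self, small_dataset):
        # 20 reactions x 5 solvents; n = 25 leaves slack above the 20 keys
        subset = coverage_sample(small_dataset, 25, seed=3)
        assert len(subset) == 25
        assert len({r.reaction_key for r in subset}) == 20
        assert len({r.solvent_key for r in subset}) == 5

    def test_full_size_is_identity(self, small_dataset):
        subset = coverage_sample(small_dataset, len(small_dataset), seed=0)
        assert subset == list(small_dataset)

    def test_deterministic_per_seed(self, small_dataset):
        a = coverage_sample(small_dataset, 40, seed=7)
        b = coverage_sample(small_dataset, 40, seed=7)
        c = coverage_sample(small_dataset, 40, seed=8)
        assert a == b
        assert a != c

    def test_fallback_below_reaction_count(self, small_dataset):
        subset = coverage_sample(small_dataset, 10, seed=1)
        assert len(subset) == 10  # plain uniform sampling, no guarantee

    def test_oversize_request_rejected(self, small_dataset):
        with pytest.raises(UsageError):
            coverage_sample(small_dataset, len(small_dataset) + 1, seed=0)


class TestWeightedSolventSample:
    def test_full_draw_selects_everything(self, small_dataset):
        subset = weighted_solvent_sample(small_dataset, per_reaction=5,
                                         weights=lambda s: 1.0, seed=0)
        assert len(subset) == len(small_dataset)

    def test_polar_solvents_oversampled(self):
        rxns = generate_reactions(100, seed=0)[::2]  # forward directions only
        from kinsolv.pairtable import PairRecord

        records = []
        for i, rxn in enumerate(rxns):  # 100 reactions x 2 solvents
            for solvent in ("O", "CC"):
                records.append(PairRecord(reaction=rxn, solvent=solvent,
                                          ddG298=0.0, ddH298=0.0,
                                          record_id=f"{i}-{solvent}"))
        weights = {"O": 10.0, "CC": 1.0}
        subset = weighted_solvent_sample(records, per_reaction=1,
                                         weights=weights, seed=5)
        polar = sum(1 for r in subset if r.solvent == "O")
        # binomial(100 draws, p=10/11): mean 90.9, sd 2.87; allow 3 sigma
        # (the coverage post-pass may swap one record)
        assert 100 <= len(subset) <= 101
        assert 81 <= polar <= 100
        assert any(r.solvent == "CC" for r in subset)  # coverage guarantee

    def test_deterministic(self, small_dataset):
        a = weighted_solvent_sample(small_dataset, 3, seed=11)
        b = weighted_solvent_sample(small_dataset, 3, seed=11)
        assert a == b

    def test_nonpositive_weight_rejected(self, small_dataset):
        with pytest.raises(UsageError):
            weighted_solvent_sample(small_dataset, 3, weights=lambda s: 0.0, seed=0)

    def test_default_weight_is_polarity_monotone(self):
        assert default_solvent_weight("O") == pytest.approx(3.0)
        assert default_solvent_weight("CCCCCC") == pytest.approx(1.0)
        assert default_solvent_weight("CCO") > default_solvent_weight("CCC")


class TestSplits:
    def test_reaction_split_takes_whole_groups(self):
        records = fixture_dataset(20, 3, seed=2)  # 40 directed x 3 solvents
        split = make_reaction_split(records, test_frac=0.05, val_frac=0.2, seed=0)
        test_idx = split.indices("test")
        assert test_idx.size == 6  # 1 undirected reaction x 2 dirs x 3 solvents
        test_keys = {records[i].reaction_key for i in test_idx}
        assert len(test_keys) == 1
        train_val_keys = {
            records[i].reaction_key
            for i in np.concatenate([split.indices("train"), split.indices("val")])
        }
        assert not (test_keys & train_val_keys)

    def test_forward_reverse_never_split_apart(self):
        records = fixture_dataset(15, 4, seed=3)
        split = make_reaction_split(records, test_frac=0.2, seed=1)
        roles_by_key = {}
        for rec, role in zip(records, split.roles):
            roles_by_key.setdefault(rec.reaction_key, set()).add(role == "test")
        for flags in roles_by_key.values():
            assert len(flags) == 1  # a key is entirely in or entirely out

    def test_solvent_split_rounds_half_up(self):
        records = fixture_dataset(5, 30, seed=4)
        split = make_solvent_split(records, test_frac=0.05, seed=2)
        test_solvents = {records[i].solvent_key for i in split.indices("test")}
        assert len(test_solvents) == 2  # 30 * 0.05 = 1.5 -> 2
        rest = {records[i].solvent_key
                for i in np.concatenate([split.indices("train"), split.indices("val")])}
        assert not (test_solvents & rest)

    def test_roles_partition_records(self, small_dataset):
        split = make_reaction_split(small_dataset, seed=5)
        counts = {role: int((split.roles == role).sum())
                  for role in ("train", "val", "test")}
        assert sum(counts.values()) == len(small_dataset)
        assert min(counts.values()) > 0

    def test_same_seed_reproducible(self, small_dataset):
        a = make_reaction_split(small_dataset, seed=9)
        b = make_reaction_split(small_dataset, seed=9)
        assert np.array_equal(a.roles, b.roles)

    def test_degenerate_fraction_rejected(self, small_dataset):
        with pytest.raises(UsageError):
            make_reaction_split(small_dataset, test_frac=0.999)

    def test_folds_are_independent_redraws(self, small_dataset):
        folds = make_folds(small_dataset, k=5, mode="reaction", seed=0)
        assert len(folds) == 5
        assert [f.seed for f in folds] == [0, 1, 2, 3, 4]
        test_sets = [frozenset(map(int, f.indices("test"))) for f in folds]
        assert len(set(test_sets)) > 1  # different seeds, generally different

    def test_single_fold(self, small_dataset):
        folds = make_folds(small_dataset, k=1, mode="solvent", seed=3)
        assert len(folds) == 1 and folds[0].mode == "solvent"

    def test_manifest_round_trip(self, tmp_path, small_dataset):
        split = make_reaction_split(small_dataset, seed=1)
        path = tmp_path / "split.csv"
        write_split_manifest(split, small_dataset, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == len(small_dataset) + 1
        assert lines[0] == "record_id,fold,role,mode,seed"
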