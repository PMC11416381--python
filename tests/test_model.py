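"""Weight training, prediction, Pearson fitness, CV, and model files."""

import numpy as np
import pytest

from regexgp.datasets import Peptide, PeptideDataset
from regexgp.motifs import MotifDatabase, MotifRecord, build_motif_db
from regexgp.model import (
    Model,
    Rule,
    kfold_fitness,
    load_model,
    pearson,
    pearson_fitness,
    predict_score,
    randomize_weights,
    save_model,
    train_model_weights,
    train_rule_weight,
)


def db_with(entries, threshold=12.5):
    records = {
        m: MotifRecord(m, v, 1 if v >= threshold else 0, 1, 1) for m, v in entries.items()
    }
    return MotifDatabase(records, threshold=threshold)


class TestTrainRuleWeight:
    def test_no_match_gives_zero(self):
        train = PeptideDataset([Peptide("AAAA", 5.0)])
        assert train_rule_weight(Rule(0, pattern="W+"), train, db_with({})) == 0.0

    def test_positive_branch_value_times_size(self):
        # one match "PKK" with value 14.0 >= 12.5: weight = +14*3
        train = PeptideDataset([Peptide("APVPKKPRLL", 14.0)])
        rule = Rule(0, pattern="[PNYIQ]K+")
        assert train_rule_weight(rule, train, db_with({"PKK": 14.0})) == pytest.approx(42.0)

    def test_negative_branch_subtracts(self):
        train = PeptideDataset([Peptide("APVPKKPRLL", 10.0)])
        rule = Rule(0, pattern="[PNYIQ]K+")
        assert train_rule_weight(rule, train, db_with({"PKK": 10.0})) == pytest.approx(-30.0)

    def test_matches_absent_from_db_contribute_nothing(self):
        train = PeptideDataset([Peptide("APVPKKPRLL", 14.0)])
        rule = Rule(0, pattern="PRLL")  # matches but not in db
        assert train_rule_weight(rule, train, db_with({"PKK": 14.0})) == 0.0

    def test_weight_sign_follows_motif_classes(self, tiny_dataset):
        db = build_motif_db(tiny_dataset)
        for pattern in ("KK", "TT", "QS"):
            w = train_rule_weight(Rule(0, pattern=pattern), tiny_dataset, db)
            rec = db.lookup(pattern)
            if rec is not None:
                assert (w >= 0) == (rec.cest_value >= db.threshold)


class TestTrainModelWeights:
    def test_rules_trained_independently(self, tiny_dataset):
        db = build_motif_db(tiny_dataset)
        model = Model([Rule(0, pattern="KK"), Rule(1, pattern="QS")])
        train_model_weights(model, tiny_dataset, db)
        for rule in model.rules:
            solo = train_rule_weight(Rule(9, pattern=rule.pattern_str), tiny_dataset, db)
            assert rule.weight == pytest.approx(solo)

    def test_order_invariance(self, tiny_dataset):
        db = build_motif_db(tiny_dataset)
        m1 = train_model_weights(
            Model([Rule(0, pattern="KK"), Rule(1, pattern="QS")]), tiny_dataset, db
        )
        m2 = train_model_weights(
            Model([Rule(1, pattern="QS"), Rule(0, pattern="KK")]), tiny_dataset, db
        )
        by_id_1 = {r.id: r.weight for r in m1.rules}
        by_id_2 = {r.id: r.weight for r in m2.rules}
        assert by_id_1 == by_id_2


class TestPredictScore:
    def test_hand_summed_examples(self):
        model = Model([Rule(0, pattern="K+", weight=2.5), Rule(1, pattern="RR", weight=-1.0)])
        assert predict_score(model, "RRKK") == pytest.approx(1.5)
        assert predict_score(model, "KKAK") == pytest.approx(2.5)
        assert predict_score(model, "WWWW") == 0.0

    def test_presence_not_count_gates_weight(self):
        model = Model([Rule(0, pattern="K", weight=1.0)])
        assert predict_score(model, "KKKKK") == pytest.approx(1.0)

    def test_linearity_in_weights(self, hand_model, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        scaled = hand_model.copy()
        for r in scaled.rules:
            r.weight *= 3.0
        for _ in range(50):
            seq = "".join(letters[rng.integers(20, size=12)])
            assert predict_score(scaled, seq) == pytest.approx(
                3.0 * predict_score(hand_model, seq)
            )


class TestPearson:
    def test_perfect_and_inverted_correlation(self):
        model = Model([Rule(0, pattern="K", weight=1.0)])
        data = PeptideDataset([Peptide("KAAA", 1.0), Peptide("AAAA", 0.0)])
        assert pearson_fitness(model, data) == pytest.approx(1.0)
        flipped = PeptideDataset([Peptide("KAAA", 0.0), Peptide("AAAA", 1.0)])
        assert pearson_fitness(model, flipped) == pytest.approx(-1.0)

    def test_degenerate_inputs_return_zero(self):
        model = Model([Rule(0, pattern="W", weight=1.0)])  # never matches
        data = PeptideDataset([Peptide("KAAA", 1.0), Peptide("AAAA", 0.0)])
        assert pearson_fitness(model, data) == 0.0

    def test_agrees_with_direct_formula_on_random_vectors(self, rng):
        for _ in range(100):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            direct = np.corrcoef(x, y)[0, 1]
            assert pearson(x, y) == pytest.approx(direct, abs=1e-12)

    def test_too_few_records_rejected(self):
        model = Model([Rule(0, pattern="K", weight=1.0)])
        with pytest.raises(ValueError):
            pearson_fitness(model, PeptideDataset([Peptide("KA", 1.0)]))


class TestKfoldFitness:
    def test_two_fold_toy_matches_bruteforce(self):
        peps = [
            Peptide("KKAA", 14.0),
            Peptide("AAKK", 13.0),
            Peptide("TTAA", 6.0),
            Peptide("AATT", 5.0),
        ]
        train = PeptideDataset(peps)
        model = Model([Rule(0, pattern="KK")])
        fitness, validation = kfold_fitness(model, train, k=2, seed=0)

        # independent brute force with the same fold assignment
        from regexgp.model import assign_folds

        folds = assign_folds(4, 2, 0)
        y = train.phenotypes
        r_tr, r_va = [], []
        for f in (0, 1):
            tr_idx = np.flatnonzero(folds != f)
            va_idx = np.flatnonzero(folds == f)
            sub = train.subset(tr_idx.tolist())
            db = build_motif_db(sub)
            w = train_rule_weight(Rule(0, pattern="KK"), sub, db)
            ps = np.array([w if "KK" in p.sequence else 0.0 for p in train])
            r_tr.append(pearson(ps[tr_idx], y[tr_idx]))
            r_va.append(pearson(ps[va_idx], y[va_idx]))
        assert fitness == pytest.approx(np.mean(r_tr))
        assert validation == pytest.approx(np.mean(r_va))

    def test_fold_assignment_reproducible(self, tiny_dataset):
        model = Model([Rule(0, pattern="KK")])
        a = kfold_fitness(model, tiny_dataset, k=2, seed=5)
        b = kfold_fitness(model, tiny_dataset, k=2, seed=5)
        assert a == b

    def test_requires_at_least_k_records(self, tiny_dataset):
        with pytest.raises(ValueError):
            kfold_fitness(Model([Rule(0, pattern="K")]), tiny_dataset, k=6)


class TestRandomizeWeights:
    def test_p_zero_leaves_model_unchanged(self, hand_model, rng):
        before = [r.weight for r in hand_model.rules]
        randomize_weights(hand_model, rng, p=0.0)
        assert [r.weight for r in hand_model.rules] == before

    def test_p_one_redraws_every_weight_in_range(self, hand_model, rng):
        randomize_weights(hand_model, rng, p=1.0)
        assert all(-10 <= r.weight <= 10 for r in hand_model.rules)

    def test_empirical_mean_near_zero(self, rng):
        model = Model([Rule(i, pattern="K") for i in range(10)])
        draws = []
        for _ in range(10_000):
            randomize_weights(model, rng, p=1.0)
            draws.extend(r.weight for r in model.rules)
        # Uniform(-10,10): sd = 20/sqrt(12); 3 standard errors
        se = (20 / np.sqrt(12)) / np.sqrt(len(draws))
        assert abs(np.mean(draws)) < 3 * se

    def test_invalid_arguments_rejected(self, hand_model, rng):
        with pytest.raises(ValueError):
            randomize_weights(hand_model, rng, p=1.5)
        with pytest.raises(ValueError):
            randomize_weights(hand_model, rng, low=5, high=-5)


class TestModelFiles:
    def test_roundtrip_preserves_scores(self, tmp_path, hand_model, rng):
        path = tmp_path / "model.csv"
        save_model(hand_model, path)
        again = load_model(path)
        assert len(again) == len(hand_model)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(letters[rng.integers(20, size=12)])
            assert predict_score(again, seq) == pytest.approx(
                predict_score(hand_model, seq)
            )

    def test_tree_side_file_roundtrip(self, tmp_path, rng):
        from regexgp.regex_tree import generate_random_tree

        model = Model(
            [Rule(i, tree=generate_random_tree(4, "grow", rng), weight=float(i))
             for i in range(3)]
        )
        path = tmp_path / "model.csv"
        save_model(model, path)
        again = load_model(path)
        assert [r.tree.pattern for r in again.rules] == [
            r.tree.pattern for r in model.rules
        ]

    def test_malformed_pattern_names_row(self, tmp_path):
        path = tmp_path / "model.csv"
        path.write_text("id,pattern,weight\n0,K+,1.0\n1,(K,2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            load_model(path)

    def test_wide_external_models_accepted(self, tmp_path):
        rows = "\n".join(f"{i},K{{{i % 9 + 1}}},1.0" for i in range(40))
        path = tmp_path / "model.csv"
        path.write_text("id,pattern,weight\n" + rows + "\n")
        assert len(load_model(path)) == 40
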