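import numpy as np
import pandas as pd
import pytest

from polyomic.errors import ScoringError, StandardizationError
from polyomic.omics_io import Layer, OmicLayerTable
from polyomic.preprocess import clr_transform
from polyomic.risk_scores import (
    ScoreModel,
    average_by_participant,
    build_score_model,
    compute_scores,
    fit_baseline,
    make_split,
    standardize,
)

from conftest import make_count_table, make_metadata


def model_with(weights, feature_ids, mean=0.0, sd=1.0, transform="clr"):
    return ScoreModel(
        layer=Layer.MGN, feature_ids=feature_ids,
        weights=np.asarray(weights, float), mean=mean, sd=sd,
        transform=transform,
    )


def clr_table(values, ids):
    df = pd.DataFrame(
        np.asarray(values, float),
        index=[f"s{i}" for i in range(len(values))],
        columns=ids,
    )
    return OmicLayerTable(Layer.MGN, df, "clr")


class TestMakeSplit:
    def _meta(self, spec):
        # spec: participant -> (n_complete, n_incomplete)
        rows = []
        complete, incomplete = set(), set()
        for pid, (nc, ni) in spec.items():
            for j in range(nc + ni):
                sid = f"{pid}_S{j}"
                rows.append(
                    dict(sample_id=sid, participant_id=pid, diagnosis="CD",
                         age=30, sex="male", race="White",
                         antibiotic_use=False, site="MGH", week=j)
                )
                (complete if j < nc else incomplete).add(sid)
        from polyomic.omics_io import CohortMetadata

        meta = CohortMetadata(pd.DataFrame(rows))
        all_ids = set(meta.sample_ids)
        inventories = {
            "MGN": all_ids, "MTS": all_ids, "VRM": all_ids,
            "MBL": all_ids - incomplete,
        }
        return meta, inventories

    def test_most_complete_participant_chosen(self):
        meta, inv = self._meta({"A": (10, 0), "B": (3, 2)})
        split = make_split(meta, inv, 1)
        assert split.validation_participants == ["A"]

    def test_tie_broken_by_fewest_incomplete(self):
        meta, inv = self._meta({"A": (5, 2), "B": (5, 4), "C": (1, 0)})
        split = make_split(meta, inv, 1)
        assert split.validation_participants == ["A"]

    def test_validation_fraction_percent(self):
        spec = {f"P{i:03d}": (2, 0) for i in range(130)}
        meta, inv = self._meta(spec)
        split = make_split(meta, inv, 30)
        assert split.validation_fraction_percent() == 23.0

    def test_partition_is_exhaustive_and_exclusive(self):
        meta, inv = self._meta({"A": (2, 1), "B": (3, 0), "C": (1, 1)})
        split = make_split(meta, inv, 2)
        assert sorted(
            split.validation_participants + split.train_participants
        ) == ["A", "B", "C"]

    def test_invalid_sizes(self):
        meta, inv = self._meta({"A": (2, 0), "B": (2, 0)})
        with pytest.raises(ValueError):
            make_split(meta, inv, 0)
        with pytest.raises(ValueError):
            make_split(meta, inv, 2)


class TestComputeScores:
    def test_zero_weights_zero_scores(self):
        t = clr_table([[1, 2], [3, 4]], ["a", "b"])
        ss = compute_scores(t, model_with([0, 0], ["a", "b"]))
        assert (ss.scores["raw"] == 0).all()

    def test_hand_dot_product(self):
        t = clr_table([[3, 1]], ["a", "b"])
        ss = compute_scores(t, model_with([1, -2], ["a", "b"]))
        assert ss.scores["raw"].iloc[0] == pytest.approx(1.0)

    def test_self_reference_standardization(self):
        rng = np.random.default_rng(0)
        t = clr_table(rng.normal(size=(30, 3)), ["a", "b", "c"])
        from polyomic.penalized_glmm import GlmmFit

        fit = GlmmFit(
            coefficients=pd.Series(
                {"(intercept)": 0.1, "a": 1.0, "b": -0.5, "c": 0.2}
            ),
            se=pd.Series(dtype=float), feature_ids=["a", "b", "c"],
            covariate_names=["(intercept)"], u={}, sigma2={},
            loglik=0.0, n_obs=30, converged=True,
        )
        model = build_score_model(fit, t)
        ss = compute_scores(t, model)
        assert ss.scores["standardized"].mean() == pytest.approx(0.0, abs=1e-10)
        assert ss.scores["standardized"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_missing_feature_errors(self):
        t = clr_table([[1.0]], ["a"])
        with pytest.raises(ScoringError):
            compute_scores(t, model_with([1, 1], ["a", "zz"]))

    def test_transform_mismatch_errors(self):
        df = pd.DataFrame([[1.0]], index=["s0"], columns=["a"])
        raw = OmicLayerTable(Layer.MGN, df, "raw")
        with pytest.raises(ScoringError):
            compute_scores(raw, model_with([1.0], ["a"]))

    def test_scoring_is_linear_in_features(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(10, 2))
        m = model_with([0.5, -1.5], ["a", "b"])
        raw1 = compute_scores(clr_table(v, ["a", "b"]), m).scores["raw"]
        raw2 = compute_scores(clr_table(3 * v, ["a", "b"]), m).scores["raw"]
        np.testing.assert_allclose(raw2.to_numpy(), 3 * raw1.to_numpy())


class TestStandardize:
    def test_hand_example(self):
        (mean, sd), z = standardize(pd.Series([1.0, 2.0, 3.0]))
        assert (mean, sd) == (2.0, 1.0)
        np.testing.assert_allclose(z.to_numpy(), [-1, 0, 1])

    def test_constant_scores_error(self):
        with pytest.raises(StandardizationError):
            standardize(pd.Series([2.0, 2.0, 2.0]))

    def test_external_reference_is_affine(self):
        ref = pd.Series([0.0, 2.0])
        (_, _), z = standardize(pd.Series([5.0]), reference=ref)
        assert z.iloc[0] == pytest.approx((5.0 - 1.0) / np.sqrt(2))


class TestAverageByParticipant:
    def test_single_and_pair_means(self, meta6):
        from polyomic.risk_scores import SampleScores

        ids = meta6.sample_ids
        std = pd.Series(0.0, index=ids)
        std[ids[0]], std[ids[1]] = 0.5, 1.5  # P00's two samples
        ss = SampleScores(
            layer=Layer.MGN,
            scores=pd.DataFrame({"raw": std, "standardized": std}),
        )
        out = average_by_participant(ss, meta6)
        assert out.loc["P00", "score"] == pytest.approx(1.0)
        assert out.loc["P00", "n_samples"] == 2

    def test_matches_brute_force_group_by(self, meta6):
        from polyomic.risk_scores import SampleScores

        rng = np.random.default_rng(2)
        vals = pd.Series(rng.normal(size=len(meta6.sample_ids)),
                         index=meta6.sample_ids)
        ss = SampleScores(
            layer=Layer.MGN,
            scores=pd.DataFrame({"raw": vals, "standardized": vals}),
        )
        out = average_by_participant(ss, meta6)
        lookup = meta6.data.set_index("sample_id")["participant_id"]
        for pid in out.index:
            expected = vals[lookup == pid].mean()
            assert out.loc[pid, "score"] == pytest.approx(expected)

    def test_averaging_standardized_differs_from_standardizing_averages(self):
        # regression guard: the pipeline averages standardized sample scores;
        # with unequal per-participant sample counts this is NOT the same as
        # standardizing the participant means
        meta = make_metadata(n_participants=4, samples_each=3)
        meta2 = meta.data.copy().iloc[:-2]  # unbalance the last participant
        from polyomic.omics_io import CohortMetadata
        from polyomic.risk_scores import SampleScores

        meta = CohortMetadata(meta2)
        rng = np.random.default_rng(3)
        raw = pd.Series(rng.normal(size=len(meta.sample_ids)),
                        index=meta.sample_ids)
        (_, _), std = standardize(raw)
        ss = SampleScores(
            layer=Layer.MGN,
            scores=pd.DataFrame({"raw": raw, "standardized": std}),
        )
        averaged_then = average_by_participant(ss, meta)["score"]
        lookup = meta.data.set_index("sample_id")["participant_id"]
        part_raw = raw.groupby(lookup.reindex(raw.index)).mean()
        (_, _), other_order = standardize(part_raw)
        assert not np.allclose(
            averaged_then.sort_index().to_numpy(),
            other_order.sort_index().to_numpy(),
        )


class TestBaseline:
    def test_prediction_uses_covariates_only(self):
        meta = make_metadata(n_participants=20, samples_each=2, n_cases=10)
        baseline = fit_baseline(meta)
        pred = baseline.predict(meta)
        assert len(pred) == len(meta.sample_ids)
        # interface contract: prediction consumes metadata alone
        import inspect

        sig = inspect.signature(baseline.predict)
        assert list(sig.parameters) == ["meta"]

    def test_null_metadata_gives_chance_auc(self):
        # diagnosis independent of all covariates by construction
        from polyomic.evaluation import roc_auc

        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(60):
                rows.append(
                    dict(sample_id=f"P{i}_S0", participant_id=f"P{i}",
                         diagnosis="CD" if rng.random() < 0.5 else "nonIBD",
                         age=float(rng.integers(20, 60)),
                         sex=("female", "male")[int(rng.integers(2))],
                         race="White", antibiotic_use=bool(rng.integers(2)),
                         site=("MGH", "Emory")[int(rng.integers(2))],
                         week=0)
                )
            from polyomic.omics_io import CohortMetadata

            meta = CohortMetadata(pd.DataFrame(rows))
            train = meta.subset_participants(meta.participants[:40])
            val = meta.subset_participants(meta.participants[40:])
            if val.participant_labels().nunique() < 2:
                continue
            baseline = fit_baseline(train)
            pred = baseline.predict_participants(val)
            labels = val.participant_labels().reindex(pred.index)
            auc, _ = roc_auc(pred.to_numpy(), labels.to_numpy())
            aucs.append(auc)
        assert 0.2 < np.mean(aucs) < 0.8


class TestScoreModelIO:
    def test_json_round_trip(self, tmp_path):
        m = model_with([0.5, -1.0], ["a", "b"], mean=0.3, sd=2.0)
        m.provenance = {"lambda": 1.5, "seed": 3}
        path = tmp_path / "m.json"
        m.to_json(path)
        back = ScoreModel.from_json(path)
        assert back.layer == m.layer
        assert back.feature_ids == m.feature_ids
        np.testing.assert_array_equal(back.weights, m.weights)
        assert (back.mean, back.sd) == (m.mean, m.sd)
        assert back.provenance["lambda"] == 1.5
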