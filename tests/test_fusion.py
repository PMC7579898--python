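import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pdscreen as pds
from pdscreen.errors import CompositionError, ParameterError
from pdscreen.fusion import HEALTHY, PD


class SequenceModel:
    """Test double replaying a fixed prediction sequence, one row at a time."""

    def __init__(self, seq):
        self.seq = list(seq)

    def predict(self, X):
        return np.array([self.seq.pop(0) for _ in range(len(X))])


class ConstantModel:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X))


def _profile(n_instances=1, width=3):
    frame = pd.DataFrame(np.zeros((n_instances, width)))
    return pds.PatientProfile("p1", frame.copy(), frame.copy())


class TestModalityVote:
    @pytest.mark.parametrize("votes,decision,score", [
        ((PD, PD, HEALTHY), PD, 2),
        ((HEALTHY, HEALTHY, HEALTHY), HEALTHY, 0),
        ((PD, PD, PD), PD, 3),
        ((PD, HEALTHY, HEALTHY), HEALTHY, 1),
    ])
    def test_two_of_three_rule(self, votes, decision, score):
        assert pds.modality_vote(votes) == (decision, score)

    @given(st.tuples(*[st.sampled_from([PD, HEALTHY])] * 3),
           st.permutations(range(3)))
    def test_permutation_invariance(self, votes, perm):
        shuffled = tuple(votes[i] for i in perm)
        assert pds.modality_vote(votes) == pds.modality_vote(shuffled)

    def test_wrong_arity(self):
        with pytest.raises(ParameterError):
            pds.modality_vote((PD, PD))


class TestFusePatient:
    def test_unanimous_pd_single_instance(self):
        models = [ConstantModel(PD)] * 3
        dec = pds.fuse_patient(_profile(), models, models)
        assert dec.final_status == PD
        assert dec.instances_used == 1
        assert dec.average_score == pytest.approx(1.0)
        assert not dec.unresolved

    def test_both_negative_is_non_pd(self):
        models = [ConstantModel(HEALTHY)] * 3
        dec = pds.fuse_patient(_profile(), models, models)
        assert dec.final_status == HEALTHY
        assert not dec.unresolved

    def test_contradiction_hand_trace(self):
        """Instance 1: voice (PD,PD,non) vs tremor (non,non,PD) contradict;
        instance 2: voice (PD,PD,PD) and tremor (PD,PD,non) agree on PD.
        Average score = (2+1+3+2)/12 = 0.667 > 0.6."""
        voice = [SequenceModel([PD, PD]), SequenceModel([PD, PD]),
                 SequenceModel([HEALTHY, PD])]
        tremor = [SequenceModel([HEALTHY, PD]), SequenceModel([HEALTHY, PD]),
                  SequenceModel([PD, HEALTHY])]
        dec = pds.fuse_patient(_profile(2), voice, tremor)
        assert dec.final_status == PD
        assert dec.instances_used == 2
        assert dec.average_score == pytest.approx(8 / 12, abs=1e-9)
        assert not dec.unresolved

    def test_exhaustion_decided_by_threshold(self):
        # persistent contradiction: voice always PD (3 votes), tremor never
        voice = [ConstantModel(PD)] * 3
        tremor = [ConstantModel(HEALTHY)] * 3
        dec = pds.fuse_patient(_profile(2), voice, tremor)
        assert dec.unresolved
        assert dec.average_score == pytest.approx(0.5)
        assert dec.final_status == HEALTHY  # 0.5 not strictly above 0.6

    def test_threshold_strictly_exceeded(self):
        # voice 3/3 PD, tremor 1/3 PD -> contradiction, average 4/6 = 0.667
        voice = [ConstantModel(PD)] * 3
        tremor = [ConstantModel(PD), ConstantModel(HEALTHY),
                  ConstantModel(HEALTHY)]
        dec = pds.fuse_patient(_profile(1), voice, tremor)
        assert dec.unresolved
        assert dec.average_score == pytest.approx(4 / 6)
        assert dec.final_status == PD

    def test_unanimity_ignores_threshold(self):
        models = [ConstantModel(PD)] * 3
        for thr in (0.0, 0.99):
            assert pds.fuse_patient(_profile(), models, models,
                                    threshold=thr).final_status == PD
        models = [ConstantModel(HEALTHY)] * 3
        for thr in (0.0, 0.99):
            assert pds.fuse_patient(_profile(), models, models,
                                    threshold=thr).final_status == HEALTHY

    def test_monotone_in_votes(self):
        """Flipping any single vote from negative to positive never flips a
        PD decision to non-PD (exhaustive over 1-instance vote tables)."""
        for votes in itertools.product([PD, HEALTHY], repeat=6):
            voice = [ConstantModel(v) for v in votes[:3]]
            tremor = [ConstantModel(v) for v in votes[3:]]
            base = pds.fuse_patient(_profile(), voice, tremor).final_status
            if base != PD:
                continue
            for i in range(6):
                if votes[i] == PD:
                    continue
                flipped = list(votes)
                flipped[i] = PD
                v2 = [ConstantModel(v) for v in flipped[:3]]
                t2 = [ConstantModel(v) for v in flipped[3:]]
                assert pds.fuse_patient(_profile(), v2, t2).final_status == PD

    def test_model_count_enforced(self):
        models = [ConstantModel(PD)] * 3
        with pytest.raises(ParameterError):
            pds.fuse_patient(_profile(), models[:2], models)

    def test_predicted_updrs_attached(self):
        models = [ConstantModel(PD)] * 3
        prof = _profile()
        prof.tremor_quantitative = [pds.TremorQuantitative(5.0, 60.0)]
        dec = pds.fuse_patient(prof, models, models)
        assert dec.predicted_updrs == 3


class TestBuildSyntheticPatients:
    def _tables(self, n_pd, n_healthy, seed=0):
        voice = pds.simulate_feature_table(n_pd, n_healthy, seed=seed)
        tremor = pds.simulate_feature_table(n_pd, n_healthy, seed=seed + 1)
        return voice, tremor

    def test_single_rows_single_profile_per_class(self):
        voice, tremor = self._tables(1, 1)
        profiles = pds.build_synthetic_patients(voice, tremor, 1, seed=0)
        assert len(profiles) == 2
        assert {p.true_status for p in profiles} == {PD, HEALTHY}

    def test_class_pure_profiles(self):
        voice, tremor = self._tables(10, 10)
        profiles = pds.build_synthetic_patients(voice, tremor, 3, seed=5)
        assert len(profiles) == 20
        for p in profiles:
            assert len(p.voice_instances) == 3
            assert len(p.tremor_instances) == 3
            # every instance comes from the profile's own class
            cls_rows = voice.features[(voice.status == p.true_status).to_numpy()]
            for _, row in p.voice_instances.iterrows():
                assert ((cls_rows == row.to_numpy()).all(axis=1)).any()

    def test_deterministic_given_seed(self):
        voice, tremor = self._tables(6, 6)
        a = pds.build_synthetic_patients(voice, tremor, 2, seed=3)
        b = pds.build_synthetic_patients(voice, tremor, 2, seed=3)
        for pa, pb in zip(a, b):
            pd.testing.assert_frame_equal(pa.voice_instances, pb.voice_instances)
            pd.testing.assert_frame_equal(pa.tremor_instances, pb.tremor_instances)

    def test_missing_class_raises(self):
        voice = pds.simulate_feature_table(5, 5, seed=0)
        tremor = pds.simulate_feature_table(5, 5, seed=1)
        pd_only = tremor.subset((tremor.status == PD).to_numpy())
        with pytest.raises(CompositionError):
            pds.build_synthetic_patients(voice, pd_only, 2, seed=0)


class TestEndToEnd:
    def test_fused_accuracy_at_least_single_modality(self):
        """On well-separated tables the fused decision must not fall more
        than 2 points below the best single-modality CV accuracy."""
        from pdscreen.cli import run_fusion_chain
        voice = pds.simulate_feature_table(40, 40, seed=21)
        from pdscreen.tremor import feature_names
        teffect = pds.default_effect_profile(feature_names(), 3.0)
        tremor = pds.simulate_feature_table(
            40, 40, feature_names=feature_names(), effect=teffect, seed=22)
        single = []
        for tab in (voice, tremor):
            rep = pds.cross_validate(tab, pds.ModelSpec("knn", {"k": 5}),
                                     folds=5, seed=1)
            single.append(rep.accuracy)
        decisions = run_fusion_chain(voice, tremor, instances=3, folds=5,
                                     seed=1)
        correct = sum(1 for d, truth in decisions if d.final_status == truth)
        fused_acc = 100.0 * correct / len(decisions)
        assert fused_acc >= max(single) - 2.0
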