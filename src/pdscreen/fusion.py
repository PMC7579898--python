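"""Multimodal late fusion: majority vote, contradiction resolution, scoring.

Each modality (voice, tremor) is judged by three trained classifiers; a
modality declares PD when at least 2 of the 3 vote PD (majority vote). A
patient profile holds ordered instances for both modalities. Instance pairs
are consumed in order: if the two modality votes agree the decision is
final; if they contradict, the next instance pair is consumed. Every
evaluated instance contributes a score out of 3 (the number of PD votes);
if the instances are exhausted without agreement the patient is declared PD
when the average score — total PD votes over all evaluated votes
(3 votes x instances x 2 modalities) — strictly exceeds the threshold
(default 60%, the majority-vote ratio 2/3 rounded down to a common
threshold). A patient is declared non-PD only when both modalities end up
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CompositionError, ParameterError
from .io_formats import LabeledFeatureTable
from .tremor import TremorQuantitative, updrs_from_quantitative

PD = "PD"
HEALTHY = "healthy"


@dataclass
class PatientProfile:
    """Ordered per-modality feature instances for one (synthetic) patient."""

    patient_id: str
    voice_instances: pd.DataFrame   # rows = instances, columns = features
    tremor_instances: pd.DataFrame
    gender: str = "unknown"
    true_status: str | None = None
    tremor_quantitative: list[TremorQuantitative] | None = None

    def __post_init__(self) -> None:
        if len(self.voice_instances) < 1 or len(self.tremor_instances) < 1:
            raise ParameterError("need >= 1 instance per modality")


@dataclass
class InstanceVotes:
    """Votes of the three models of one modality on one instance."""

    modality: str
    votes: tuple[str, str, str]
    decision: str
    score: int


@dataclass
class FusionDecision:
    """Full vote trace and final status for one patient."""

    patient_id: str
    trace: list[InstanceVotes]
    instances_used: int
    average_score: float        # fraction of PD votes among evaluated votes
    final_status: str
    unresolved: bool            # True if decided by the score threshold
    predicted_updrs: int | None = None


def modality_vote(predictions: Sequence[str]) -> tuple[str, int]:
    """2-of-3 majority vote; returns (decision, number of PD votes)."""
    if len(predictions) != 3:
        raise ParameterError(f"expected exactly 3 predictions, got {len(predictions)}")
    score = sum(1 for p in predictions if p == PD)
    return (PD if score >= 2 else HEALTHY), score


def _predict_one(models, row: np.ndarray) -> list[str]:
    out = []
    for m in models:
        label = m.predict(row[None, :])[0]
        out.append(str(label))
    return out


def fuse_patient(profile: PatientProfile, voice_models: Sequence,
                 tremor_models: Sequence, threshold: float = 0.6,
                 ) -> FusionDecision:
    """Run the combined-decision procedure for one patient.

    ``voice_models`` / ``tremor_models`` are the three trained classifiers
    per modality (anything with a ``predict`` method). Instance pairs are
    consumed in order until the two modality votes agree; on exhaustion the
    average score against ``threshold`` (strict >) breaks the tie and the
    decision is flagged ``unresolved``.
    """
    if len(voice_models) != 3 or len(tremor_models) != 3:
        raise ParameterError("exactly 3 trained models per modality are required")
    if not 0 <= threshold <= 1:
        raise ParameterError(f"threshold must lie in [0, 1], got {threshold}")
    n_pairs = min(len(profile.voice_instances), len(profile.tremor_instances))
    trace: list[InstanceVotes] = []
    total_score = 0
    used = 0
    agreed: str | None = None
    agree_index: int | None = None
    for i in range(n_pairs):
        vrow = profile.voice_instances.iloc[i].to_numpy(dtype=float)
        trow = profile.tremor_instances.iloc[i].to_numpy(dtype=float)
        v_votes = _predict_one(voice_models, vrow)
        t_votes = _predict_one(tremor_models, trow)
        v_dec, v_score = modality_vote(v_votes)
        t_dec, t_score = modality_vote(t_votes)
        trace.append(InstanceVotes("voice", tuple(v_votes), v_dec, v_score))
        trace.append(InstanceVotes("tremor", tuple(t_votes), t_dec, t_score))
        total_score += v_score + t_score
        used = i + 1
        if v_dec == t_dec:
            agreed = v_dec
            agree_index = i
            break
    average = total_score / (3.0 * used * 2.0)
    if agreed is not None:
        final = agreed
        unresolved = False
    else:
        final = PD if average > threshold else HEALTHY
        unresolved = True
    predicted_updrs = None
    if final == PD and profile.tremor_quantitative:
        idx = agree_index if agree_index is not None else 0
        idx = min(idx, len(profile.tremor_quantitative) - 1)
        predicted_updrs = updrs_from_quantitative(
            profile.tremor_quantitative[idx]).level
    return FusionDecision(profile.patient_id, trace, used, float(average),
                          final, unresolved, predicted_updrs)


def build_synthetic_patients(voice_rows: LabeledFeatureTable,
                             tremor_rows: LabeledFeatureTable,
                             instances_per_patient: int,
                             seed: int = 0) -> list[PatientProfile]:
    """Compose class-pure patient profiles from labelled feature tables.

    For each class (PD, healthy) the number of patients equals the smaller
    per-class row count of the two tables; each patient's instances are
    drawn with replacement from that class's rows of each table. PD and
    healthy rows are never mixed within a patient. Reproducible given seed.
    """
    if instances_per_patient < 1:
        raise ParameterError("instances_per_patient must be >= 1")
    rng = np.random.default_rng(seed)
    profiles: list[PatientProfile] = []
    for cls in (PD, HEALTHY):
        v_mask = (voice_rows.status == cls).to_numpy()
        t_mask = (tremor_rows.status == cls).to_numpy()
        if not v_mask.any() or not t_mask.any():
            raise CompositionError(f"class {cls!r} missing from one of the tables")
        v_feat = voice_rows.features[v_mask]
        t_feat = tremor_rows.features[t_mask]
        n_patients = min(len(v_feat), len(t_feat))
        for i in range(n_patients):
            vi = rng.integers(0, len(v_feat), size=instances_per_patient)
            ti = rng.integers(0, len(t_feat), size=instances_per_patient)
            profiles.append(PatientProfile(
                patient_id=f"synth-{cls}-{i:03d}",
                voice_instances=v_feat.iloc[vi].reset_index(drop=True),
                tremor_instances=t_feat.iloc[ti].reset_index(drop=True),
                true_status=cls,
            ))
    return profiles
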