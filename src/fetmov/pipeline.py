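"""The four algorithm variants, wired end to end.

* **A1** — segmentation on the raw Z axis, STFT spectrogram image, CNN.
* **A2** — high-pass filter, segmentation, STFT spectrogram image, CNN.
* **A3** — as A2, but the spectrogram is factorized (V ~= WH) and the
  rendered basis matrix W (64 x r) feeds the CNN.
* **A4** — as A3 but with the rendered abundance matrix H (r x 26).

``run_algorithm`` executes one variant on a corpus under a single seed and
returns an :class:`EvalReport` (confusion matrix + one-vs-rest rates +
config fingerprint); identical (corpus, config, seed) triples reproduce
byte-identical report JSON.  ``run_detection`` applies a trained model to
one session in application mode (threshold segmentation) and returns the
kick count.  ``compare_algorithms`` runs several variants under a shared
split seed, globally or per subject.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .classifier import (
    CNNSpec,
    TrainedModel,
    predict,
    stratified_split,
    train_cnn,
)
from .evaluation import ConfusionMatrix3, RateReport, confusion_matrix, per_class_rates
from .features import nnmf_factorize, render_matrix_rgb, stft_magnitude
from .preprocess import FilterSpec, highpass_filter, select_z_axis
from .segmentation import (
    LabeledDataset,
    MovementClass,
    build_training_set,
    detect_candidate_peaks,
    extract_window,
)
from .session_io import RawSession
from .synth import SynthCorpus

__all__ = [
    "ALGORITHMS",
    "AlgorithmSpec",
    "PipelineConfig",
    "EvalReport",
    "featurize_dataset",
    "run_algorithm",
    "run_detection",
    "compare_algorithms",
]


@dataclass(frozen=True)
class AlgorithmSpec:
    """One of the four fixed pipeline variants."""

    id: str
    use_filter: bool
    feature: str  # "spectrogram" | "nnmf_W" | "nnmf_H"

    def __post_init__(self) -> None:
        if self.feature not in ("spectrogram", "nnmf_W", "nnmf_H"):
            raise ValueError(f"unknown feature kind {self.feature!r}")


ALGORITHMS: dict[str, AlgorithmSpec] = {
    "A1": AlgorithmSpec("A1", use_filter=False, feature="spectrogram"),
    "A2": AlgorithmSpec("A2", use_filter=True, feature="spectrogram"),
    "A3": AlgorithmSpec("A3", use_filter=True, feature="nnmf_W"),
    "A4": AlgorithmSpec("A4", use_filter=True, feature="nnmf_H"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs besides the corpus and the seed."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    search_back_s: float = 5.0
    nnmf_rank: int = 5
    nnmf_max_iter: int = 200
    nnmf_tol: float = 1e-4
    cnn: CNNSpec = field(default_factory=CNNSpec)
    train_frac: float = 0.8

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EvalReport:
    """Evaluation of one algorithm run on one corpus."""

    algorithm: str
    cm: ConfusionMatrix3
    rates: RateReport
    config_fingerprint: str
    seed: int
    n_train: int
    n_test: int

    def to_json(self) -> str:
        """Deterministic JSON rendering (byte-identical for equal runs)."""
        return json.dumps(
            {
                "algorithm": self.algorithm,
                "confusion_matrix": self.cm.counts.tolist(),
                "tpr": self.rates.tpr,
                "fpr": self.rates.fpr,
                "support": self.rates.support,
                "config_fingerprint": self.config_fingerprint,
                "seed": self.seed,
                "n_train": self.n_train,
                "n_test": self.n_test,
            },
            sort_keys=True,
        )


def _prepare_traces(sessions: list[RawSession], algo: AlgorithmSpec,
                    config: PipelineConfig):
    pairs = []
    for sess in sessions:
        trace = select_z_axis(sess)
        if algo.use_filter:
            trace = highpass_filter(trace, config.filter)
        pairs.append((sess, trace))
    return pairs


def featurize_dataset(
    dataset: LabeledDataset,
    algo: AlgorithmSpec,
    config: PipelineConfig,
    seed: int = 0,
    fs: float = 280.0,
) -> np.ndarray:
    """Per-realization feature images (N, H, W, 3) for an algorithm variant.

    NNMF runs per realization with a seed derived deterministically from
    the run seed and the realization position.
    """
    feats = []
    for i, r in enumerate(dataset.realizations):
        V = stft_magnitude(r, fs=fs)
        if algo.feature == "spectrogram":
            mat = V.V
        else:
            res = nnmf_factorize(
                V,
                rank=config.nnmf_rank,
                seed=(seed * 100003 + i) % (2**31),
                max_iter=config.nnmf_max_iter,
                tol=config.nnmf_tol,
            )
            mat = res.W if algo.feature == "nnmf_W" else res.H
        feats.append(render_matrix_rgb(mat).pixels)
    return np.stack(feats)


def segment_corpus(corpus: SynthCorpus, algo: AlgorithmSpec,
                   config: PipelineConfig, seed: int = 0) -> LabeledDataset:
    """Annotation-mode segmentation of a whole corpus for one variant."""
    pairs = _prepare_traces(corpus.sessions, algo, config)
    return build_training_set(
        pairs,
        search_back_s=config.search_back_s,
        n_respiratory_per_session=corpus.n_respiratory_per_session,
        seed=seed,
    )


def run_algorithm(
    corpus: SynthCorpus,
    algo: AlgorithmSpec | str,
    config: PipelineConfig | None = None,
    seed: int = 0,
    dataset: LabeledDataset | None = None,
    features: np.ndarray | None = None,
) -> EvalReport:
    """Execute one variant end to end and evaluate on its held-out split.

    Stages: [filter?] -> annotation-mode segmentation -> STFT ->
    [NNMF(W|H)?] -> CNN train/test -> confusion matrix and rates.
    ``dataset``/``features`` allow sharing precomputed stages between
    variants that use identical upstream configurations.
    """
    if isinstance(algo, str):
        algo = ALGORITHMS[algo]
    if config is None:
        config = PipelineConfig()
    fs = corpus.sessions[0].fs
    if dataset is None:
        dataset = segment_corpus(corpus, algo, config, seed=seed)
    if features is None:
        features = featurize_dataset(dataset, algo, config, seed=seed, fs=fs)
    labels = dataset.labels
    split = stratified_split(labels, train_frac=config.train_frac, seed=seed)
    spec = config.cnn.with_input_shape(features.shape[1:])
    model = train_cnn(features, labels, split, spec, seed=seed)
    pred, _ = predict(model, features[split.test_idx])
    cm = confusion_matrix(labels[split.test_idx], pred)
    return EvalReport(
        algorithm=algo.id,
        cm=cm,
        rates=per_class_rates(cm),
        config_fingerprint=config.fingerprint(),
        seed=seed,
        n_train=int(split.train_idx.size),
        n_test=int(split.test_idx.size),
    )


def run_detection(
    session: RawSession,
    model: TrainedModel,
    config: PipelineConfig | None = None,
    algo: AlgorithmSpec | str = "A2",
    threshold: float | None = None,
    seed: int = 0,
) -> dict:
    """Application-mode kick counting for one session.

    Threshold segmentation (adaptive unless ``threshold`` is given) cuts
    candidate realizations; the trained model classifies each; the kick
    count is the number of class-1 predictions, reported with their event
    times in seconds.
    """
    if isinstance(algo, str):
        algo = ALGORITHMS[algo]
    if config is None:
        config = PipelineConfig()
    trace = select_z_axis(session)
    if algo.use_filter:
        trace = highpass_filter(trace, config.filter)
    peaks = detect_candidate_peaks(trace, threshold=threshold)
    realizations = []
    kept_peaks = []
    for p in peaks:
        try:
            realizations.append(extract_window(trace, int(p)))
            kept_peaks.append(int(p))
        except IndexError:
            continue
    if not realizations:
        return {"kick_count": 0, "kick_times_s": [], "n_candidates": 0}
    ds = LabeledDataset(realizations=realizations)
    feats = featurize_dataset(ds, algo, config, seed=seed, fs=session.fs)
    pred, _ = predict(model, feats)
    kick_times = [
        kept_peaks[i] / session.fs
        for i in range(len(pred))
        if pred[i] == MovementClass.FETAL
    ]
    return {
        "kick_count": len(kick_times),
        "kick_times_s": kick_times,
        "n_candidates": len(realizations),
    }


def compare_algorithms(
    corpus: SynthCorpus,
    algo_ids: list[str],
    scope: str = "global",
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run several variants under a shared split seed.

    ``scope="global"`` trains one model per variant over all subjects and
    returns {algo_id: EvalReport}.  ``scope="per_subject"`` trains and
    tests within each subject separately and additionally returns the
    per-subject class-1 TPR table; subjects whose data lack a class (too
    few realizations to split) are skipped with a warning.
    """
    if config is None:
        config = PipelineConfig()
    if scope == "global":
        return {aid: run_algorithm(corpus, aid, config, seed=seed)
                for aid in algo_ids}
    if scope != "per_subject":
        raise ValueError("scope must be 'global' or 'per_subject'")
    if len(corpus.subject_ids) < 2:
        raise ValueError("per-subject scope needs >= 2 subjects")
    reports: dict[str, dict[str, EvalReport]] = {aid: {} for aid in algo_ids}
    tpr_table: dict[str, dict[str, float | None]] = {}
    for sid in corpus.subject_ids:
        keep = [k for k, s in enumerate(corpus.sessions)
                if s.meta.subject_id == sid]
        sub = SynthCorpus(
            sessions=[corpus.sessions[k] for k in keep],
            truths=[corpus.truths[k] for k in keep],
            subject_ids=[sid],
            gestational_ages={sid: corpus.gestational_ages[sid]},
            n_respiratory_per_session=[corpus.n_respiratory_per_session[k]
                                       for k in keep],
            seed=corpus.seed,
        )
        tpr_table[sid] = {}
        for aid in algo_ids:
            try:
                rep = run_algorithm(sub, aid, config, seed=seed)
            except ValueError as exc:
                warnings.warn(f"subject {sid} skipped for {aid}: {exc}",
                              stacklevel=2)
                tpr_table[sid][aid] = None
                continue
            reports[aid][sid] = rep
            tpr_table[sid][aid] = rep.rates.tpr[int(MovementClass.FETAL)]
    return {"reports": reports, "tpr_per_subject": tpr_table}
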