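"""Classification protocols and the sensor-ablation analysis.

Three protocols evaluate a feature family (TSG, BF, or their concatenation)
with a leaf-posterior random forest, per subject-session, over seeded
random train/test splits of the windows:

* ``in_session`` — stratified split at a training proportion p; feature
  maps (TSG embedding, BF PCA) are fit on training windows only.
* ``non_constant_querying`` — fixed 80/20 split; the (unsupervised) feature
  maps see the full 80% while the classifier is trained on a labeled
  fraction r of it, so the labeled share of the session is 0.8 * r.
* ``transfer`` — feature maps and classifier come from a source session;
  target windows are mapped through the source out-of-sample extension, a
  fraction f of the target training windows re-estimates the forest's leaf
  posteriors (f = 0 is zero-shot), and the held-out target 20% is scored.

Feature maps never see test windows or any labels.  Every replicate's
seeds derive from (config seed, session index, replicate) only, so scores
are replayable and settings sharing a split (e.g. querying at r = 1 and
in-session at p = 0.8) are exactly paired.

The ablation analysis re-runs the in-session protocol on every admissible
channel subset of a pool and ranks channels (and channel pairs) by the
mean accuracy of the subsets containing them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import train_test_split

from .bands import BandPowerTransformer, BandScheme, default_scheme, \
    estimate_band_powers, normalize_and_flatten
from .model import LeafPosteriorForest, balanced_accuracy
from .preprocess import EEGRecording, bandpass_filter, window_series
from .tsg import TSGTransformer, correlation_graphs

__all__ = [
    "ProtocolConfig", "SessionData", "ExperimentResult", "AblationResult",
    "build_sessions", "in_session", "non_constant_querying", "transfer",
    "transfer_source_targets", "cross_subject_transfer",
    "cross_subject_summary", "sensor_ablation", "ablation_subsets",
    "channel_importance", "summarize_table",
]

FEATURE_SETS = ("tsg", "bf", "tsg+bf")


@dataclass
class ProtocolConfig:
    """Settings shared by the classification protocols.

    ``classifier`` is a prototype estimator cloned for every replicate with
    its ``random_state`` set from the replicate seed; it defaults to the
    standard 100-tree :class:`LeafPosteriorForest`.
    """

    feature_set: str = "tsg+bf"
    train_proportions: tuple = (0.8,)
    labeled_ratios: tuple = (1.0,)
    finetune_fractions: tuple = (0.0,)
    n_replicates: int = 20
    seed: int = 0
    metric: str = "balanced"
    n_elbows: int = 2
    block_split: bool = False
    scheme: BandScheme | None = None
    classifier: LeafPosteriorForest | None = None

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        for name in ("train_proportions", "labeled_ratios", "finetune_fractions"):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.metric not in ("balanced", "standard"):
            raise ValueError("metric must be 'balanced' or 'standard'")


@dataclass
class SessionData:
    """All windows of one subject-session, with per-window labels."""

    windows: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str
    session_id: str
    seed_key: int = 0

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def build_sessions(
    recordings: list[EEGRecording],
    window_seconds: float = 2.5,
    overlap_seconds: float = 0.0,
    hp_hz: float = 0.5,
    lp_hz: float = 30.0,
) -> list[SessionData]:
    """Filter, window and group recordings into per-session datasets.

    The band-pass filter is applied to each full recording before
    windowing.  Recordings sharing (subject_id, session_id) are pooled;
    ``seed_key`` is the session's index in first-appearance order and
    anchors all replicate seeds.
    """
    grouped: dict[tuple[str, str], list[EEGRecording]] = {}
    for rec in recordings:
        grouped.setdefault((rec.subject_id, rec.session_id), []).append(rec)
    sessions = []
    for key_idx, ((subj, sess), recs) in enumerate(grouped.items()):
        all_windows, all_labels = [], []
        for rec in recs:
            filtered = bandpass_filter(rec, hp_hz, lp_hz)
            w = int(round(window_seconds * rec.sampling_rate))
            h = int(round(overlap_seconds * rec.sampling_rate))
            ws = window_series(filtered, w, h)
            all_windows.append(ws.windows)
            all_labels.append(ws.labels)
        sessions.append(SessionData(
            windows=np.concatenate(all_windows),
            labels=np.concatenate(all_labels),
            sampling_rate=recs[0].sampling_rate,
            channel_labels=list(recs[0].channel_labels),
            subject_id=subj, session_id=sess, seed_key=key_idx,
        ))
    return sessions


class _SessionCache:
    """Per-session correlation graphs and normalized band features.

    Both are per-window and label-free, so they can be computed once and
    sliced per split/subset without changing any result: a channel-subset
    correlation matrix is the corresponding submatrix, and per-channel
    normalized band features are independent across channels.
    """

    def __init__(self, session: SessionData, scheme: BandScheme | None = None):
        self.session = session
        self.scheme = scheme or default_scheme()
        self._graphs: np.ndarray | None = None
        self._band3d: np.ndarray | None = None
        self.subset: np.ndarray | None = None
        self._parent: "_SessionCache" | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.session.labels

    def graphs(self) -> np.ndarray:
        root = self._parent or self
        if root._graphs is None:
            root._graphs = correlation_graphs(root.session.windows)
        g = root._graphs
        if self.subset is not None:
            g = g[np.ix_(range(len(g)), self.subset, self.subset)]
        return g

    def band_features(self) -> np.ndarray:
        root = self._parent or self
        if root._band3d is None:
            powers = np.stack([
                estimate_band_powers(w, root.session.sampling_rate, root.scheme)
                for w in root.session.windows
            ])
            n_w, n_c, I = powers.shape
            root._band3d = normalize_and_flatten(powers).reshape(n_w, n_c, I)
        b = root._band3d
        if self.subset is not None:
            b = b[:, self.subset, :]
        return b.reshape(b.shape[0], -1)

    def restrict(self, channels) -> "_SessionCache":
        sub = _SessionCache(self.session, self.scheme)
        sub.subset = np.asarray(channels, dtype=int)
        sub._parent = self._parent or self
        return sub


class _FeatureMaps:
    """The unsupervised feature maps of one training split."""

    def __init__(self, feature_set: str, n_elbows: int):
        self.feature_set = feature_set
        self.n_elbows = n_elbows

    def fit(self, cache: _SessionCache, train_idx: np.ndarray) -> "_FeatureMaps":
        if "tsg" in self.feature_set:
            self.tsg_ = TSGTransformer(
                precomputed=True, n_elbows=self.n_elbows
            ).fit(cache.graphs()[train_idx])
        if "bf" in self.feature_set:
            self._bf_train = cache.band_features()[train_idx]
            self.bf_ = BandPowerTransformer(
                precomputed=True, n_elbows=self.n_elbows
            ).fit(self._bf_train)
        return self

    def training_features(self) -> np.ndarray:
        parts = []
        if "tsg" in self.feature_set:
            parts.append(self.tsg_.embedding_)
        if "bf" in self.feature_set:
            parts.append(self.bf_.transform(self._bf_train))
        return np.hstack(parts)

    def transform(self, cache: _SessionCache, idx: np.ndarray) -> np.ndarray:
        parts = []
        if "tsg" in self.feature_set:
            parts.append(self.tsg_.transform(cache.graphs()[idx]))
        if "bf" in self.feature_set:
            parts.append(self.bf_.transform(cache.band_features()[idx]))
        return np.hstack(parts)


def _replicate_seeds(config_seed: int, seed_key: int, replicate: int):
    ss = np.random.SeedSequence((config_seed, seed_key, replicate))
    split, clf, labeled = (int(s) & 0x7FFFFFFF for s in ss.generate_state(3))
    return split, clf, labeled


def _score(y_true, y_pred, metric: str) -> float:
    if metric == "balanced":
        return balanced_accuracy(y_true, y_pred)
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def _stratified_split(indices: np.ndarray, labels: np.ndarray,
                      train_size: float, seed: int):
    """Stratified split; returns None when a class cannot appear on a side."""
    try:
        tr, te = train_test_split(indices, train_size=train_size,
                                  stratify=labels, random_state=seed)
    except ValueError:
        return None
    tr, te = np.sort(tr), np.sort(te)
    if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
        return None
    return tr, te


def _block_split(indices: np.ndarray, labels: np.ndarray,
                 train_size: float, seed: int):
    """Leakage-averse variant: per class, the test set is one contiguous
    block of windows at a seeded random offset, so adjacent (correlated)
    windows rarely straddle the train/test boundary."""
    rng = np.random.default_rng(seed)
    test_parts = []
    for c in np.unique(labels):
        idx_c = indices[labels[indices] == c]
        n_test = int(round((1.0 - train_size) * len(idx_c)))
        if n_test < 1 or n_test >= len(idx_c):
            return None
        start = int(rng.integers(0, len(idx_c) - n_test + 1))
        test_parts.append(idx_c[start:start + n_test])
    te = np.sort(np.concatenate(test_parts))
    tr = np.setdiff1d(indices, te)
    if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
        return None
    return tr, te


def _split(config: "ProtocolConfig", indices, labels, train_size, seed):
    splitter = _block_split if config.block_split else _stratified_split
    return splitter(indices, labels, train_size, seed)


def _prototype(config: ProtocolConfig) -> LeafPosteriorForest:
    return config.classifier if config.classifier is not None \
        else LeafPosteriorForest()


@dataclass
class ExperimentResult:
    """Per-replicate scores plus cohort aggregation helpers.

    ``records`` has one row per (subject, session, setting, replicate) with
    the replicate seed and score.  The cohort standard error at a setting
    is sd(per-subject mean scores) / sqrt(n_subjects).
    """

    records: pd.DataFrame
    metric: str = "balanced"

    def subject_means(self, setting=None) -> pd.Series:
        df = self.records
        if setting is not None:
            df = df[df["setting"] == setting]
        return df.groupby("subject_id")["score"].mean()

    def cohort_mean(self, setting=None) -> float:
        return float(self.subject_means(setting).mean())

    def cohort_se(self, setting=None) -> float:
        m = self.subject_means(setting)
        if len(m) < 2:
            return float("nan")
        return float(m.std(ddof=1) / np.sqrt(len(m)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for setting in sorted(self.records["setting"].unique()):
            rows.append({
                "setting": setting,
                "mean": self.cohort_mean(setting),
                "se": self.cohort_se(setting),
                "n_subjects": self.records[
                    self.records["setting"] == setting]["subject_id"].nunique(),
            })
        return pd.DataFrame(rows)


def _run_split_protocol(caches, config, settings, labeled_selector):
    """Shared driver for in_session and non_constant_querying."""
    proto = _prototype(config)
    rows = []
    for cache in caches:
        sess = cache.session
        labels = cache.labels
        idx = np.arange(sess.n_windows)
        for setting, train_size in settings:
            for rep in range(config.n_replicates):
                split_seed, clf_seed, labeled_seed = _replicate_seeds(
                    config.seed, sess.seed_key, rep)
                split = _split(config, idx, labels, train_size, split_seed)
                if split is None:
                    warnings.warn(
                        f"skipping replicate {rep} for "
                        f"{sess.subject_id}/{sess.session_id} at setting "
                        f"{setting}: a class would be empty", RuntimeWarning)
                    continue
                tr, te = split
                labeled_pos = labeled_selector(
                    setting, labels[tr], labeled_seed)
                if labeled_pos is None:
                    warnings.warn(
                        f"skipping replicate {rep}: labeled subset would "
                        "miss a class", RuntimeWarning)
                    continue
                maps = _FeatureMaps(config.feature_set, config.n_elbows
                                    ).fit(cache, tr)
                F_tr = maps.training_features()[labeled_pos]
                y_tr = labels[tr][labeled_pos]
                F_te = maps.transform(cache, te)
                clf = clone(proto)
                clf.set_params(random_state=clf_seed)
                clf.fit(F_tr, y_tr)
                score = _score(labels[te], clf.predict(F_te), config.metric)
                rows.append({
                    "subject_id": sess.subject_id,
                    "session_id": sess.session_id,
                    "setting": setting, "replicate": rep,
                    "seed": split_seed, "score": score,
                })
    return ExperimentResult(records=pd.DataFrame(rows), metric=config.metric)


def in_session(sessions: list[SessionData], config: ProtocolConfig,
               _caches=None) -> ExperimentResult:
    """In-session protocol over ``config.train_proportions``."""
    caches = _caches or [_SessionCache(s, config.scheme) for s in sessions]

    def all_labeled(setting, y_tr, seed):
        return np.arange(len(y_tr))

    settings = [(p, p) for p in config.train_proportions]
    return _run_split_protocol(caches, config, settings, all_labeled)


def non_constant_querying(sessions: list[SessionData],
                          config: ProtocolConfig) -> ExperimentResult:
    """Semi-supervised protocol over ``config.labeled_ratios``.

    The train/test split is always 80/20 and shares its seed stream with
    ``in_session`` at p = 0.8, so r = 1 reproduces that experiment
    replicate-for-replicate.
    """
    caches = [_SessionCache(s, config.scheme) for s in sessions]

    def select_labeled(ratio, y_tr, seed):
        pos = np.arange(len(y_tr))
        if ratio >= 1.0:
            return pos
        try:
            lab, _ = train_test_split(pos, train_size=ratio, stratify=y_tr,
                                      random_state=seed)
        except ValueError:
            return None
        if len(np.unique(y_tr[lab])) < 2:
            return None
        return np.sort(lab)

    settings = [(r, 0.8) for r in config.labeled_ratios]
    return _run_split_protocol(caches, config, settings, select_labeled)


def transfer(source: SessionData, target: SessionData,
             config: ProtocolConfig, _source_cache=None,
             _target_cache=None) -> ExperimentResult:
    """Session-to-session transfer over ``config.finetune_fractions``.

    Per replicate, both sessions are split 80/20 with their own seed
    streams; feature maps and the forest are fit on the source training
    windows, the target is mapped through the source out-of-sample
    extension, a fraction f of the target training windows re-estimates
    the leaf posteriors (f = 0: zero-shot), and the target test split is
    scored.  Self-transfer at f = 0 is therefore identical to in-session
    at p = 0.8.
    """
    if source.n_channels != target.n_channels:
        raise ValueError("source and target channel counts differ")
    s_cache = _source_cache or _SessionCache(source, config.scheme)
    t_cache = _target_cache or _SessionCache(target, config.scheme)
    proto = _prototype(config)
    rows = []
    for rep in range(config.n_replicates):
        s_split_seed, s_clf_seed, _ = _replicate_seeds(
            config.seed, source.seed_key, rep)
        t_split_seed, _, t_labeled_seed = _replicate_seeds(
            config.seed, target.seed_key, rep)
        s_split = _split(config, np.arange(source.n_windows),
                         source.labels, 0.8, s_split_seed)
        t_split = _split(config, np.arange(target.n_windows),
                         target.labels, 0.8, t_split_seed)
        if s_split is None or t_split is None:
            warnings.warn(f"skipping transfer replicate {rep}: degenerate split",
                          RuntimeWarning)
            continue
        s_tr, _ = s_split
        t_tr, t_te = t_split
        maps = _FeatureMaps(config.feature_set, config.n_elbows).fit(s_cache, s_tr)
        clf = clone(proto)
        clf.set_params(random_state=s_clf_seed)
        clf.fit(maps.training_features(), source.labels[s_tr])
        F_t_train = maps.transform(t_cache, t_tr)
        F_t_test = maps.transform(t_cache, t_te)
        y_t_train = target.labels[t_tr]
        for f in config.finetune_fractions:
            if f <= 0.0:
                model = clf
            else:
                pos = np.arange(len(t_tr))
                if f >= 1.0:
                    sel = pos
                else:
                    try:
                        sel, _ = train_test_split(
                            pos, train_size=f, stratify=y_t_train,
                            random_state=t_labeled_seed)
                    except ValueError:
                        warnings.warn(
                            f"skipping fine-tune fraction {f} in replicate "
                            f"{rep}: too few windows", RuntimeWarning)
                        continue
                model = clf.fine_tune(F_t_train[sel], y_t_train[sel])
            score = _score(target.labels[t_te], model.predict(F_t_test),
                           config.metric)
            rows.append({
                "subject_id": target.subject_id,
                "session_id": target.session_id,
                "source_subject": source.subject_id,
                "source_session": source.session_id,
                "setting": f, "replicate": rep,
                "seed": t_split_seed, "score": score,
            })
    return ExperimentResult(records=pd.DataFrame(rows), metric=config.metric)


def transfer_source_targets(
    sessions: list[SessionData],
) -> list[tuple[SessionData, list[SessionData]]]:
    """Cross-subject harness plan: per target session, its source sessions.

    Sources are every session whose subject differs from the target's, so a
    cohort of n subjects with one session each yields n - 1 sources per
    target and n subjects with two sessions each yields 2n - 2.
    """
    return [
        (t, [s for s in sessions if s.subject_id != t.subject_id])
        for t in sessions
    ]


def cross_subject_transfer(sessions: list[SessionData],
                           config: ProtocolConfig) -> pd.DataFrame:
    """Evaluate every cross-subject source->target pair.

    Returns one row per (target, source, fine-tune fraction) holding the
    mean score over replicates.
    """
    caches = {id(s): _SessionCache(s, config.scheme) for s in sessions}
    rows = []
    for target, sources in transfer_source_targets(sessions):
        for source in sources:
            res = transfer(source, target, config,
                           _source_cache=caches[id(source)],
                           _target_cache=caches[id(target)])
            for f, grp in res.records.groupby("setting"):
                rows.append({
                    "target_subject": target.subject_id,
                    "target_session": target.session_id,
                    "source_subject": source.subject_id,
                    "source_session": source.session_id,
                    "setting": f, "score": float(grp["score"].mean()),
                })
    return pd.DataFrame(rows)


def cross_subject_summary(pair_scores: pd.DataFrame):
    """Per-target mean/min/max over sources, plus cohort averages.

    Returns ``(per_target, cohort)`` data frames; the cohort frame averages
    the per-target statistics across targets per fine-tune fraction.
    """
    g = pair_scores.groupby(
        ["target_subject", "target_session", "setting"])["score"]
    per_target = g.agg(mean="mean", min="min", max="max",
                       n_sources="count").reset_index()
    cohort = per_target.groupby("setting")[["mean", "min", "max"]] \
        .mean().reset_index()
    return per_target, cohort


def ablation_subsets(channel_pool, min_size: int) -> list[tuple[int, ...]]:
    """All subsets of the pool with at least ``min_size`` channels."""
    pool = sorted(int(c) for c in channel_pool)
    if len(set(pool)) != len(pool):
        raise ValueError("channel_pool contains duplicates")
    out = []
    for size in range(min_size, len(pool) + 1):
        out.extend(itertools.combinations(pool, size))
    return out


@dataclass
class AblationResult:
    """Subset accuracies and derived channel/pair importances."""

    subset_scores: dict
    size_summary: pd.DataFrame
    channel_importance: pd.Series
    pair_importance: pd.Series
    channel_ranks: list = field(default_factory=list)
    pair_ranks: list = field(default_factory=list)


def channel_importance(subset_scores: dict) -> AblationResult:
    """Rank channels and channel pairs by mean accuracy over subsets.

    A channel's importance is the average accuracy of every evaluated
    subset containing it, likewise for pairs; ranks are descending by
    importance with ties broken by channel index (stable sort).
    """
    chan_scores: dict[int, list[float]] = {}
    pair_scores: dict[tuple[int, int], list[float]] = {}
    for subset, score in subset_scores.items():
        for c in subset:
            chan_scores.setdefault(c, []).append(score)
        for pair in itertools.combinations(sorted(subset), 2):
            pair_scores.setdefault(pair, []).append(score)
    chan_imp = pd.Series({c: float(np.mean(v)) for c, v in chan_scores.items()},
                         name="importance").sort_index()
    pair_imp = pd.Series({p: float(np.mean(v)) for p, v in pair_scores.items()},
                         name="importance")
    chan_ranks = sorted(chan_imp.index, key=lambda c: (-chan_imp[c], c))
    pair_ranks = sorted(pair_imp.index, key=lambda p: (-pair_imp[p], p))

    sizes = sorted({len(s) for s in subset_scores})
    size_rows = []
    for size in sizes:
        vals = np.array([v for s, v in subset_scores.items() if len(s) == size])
        size_rows.append({
            "size": size, "mean": float(vals.mean()),
            "q05": float(np.quantile(vals, 0.05)),
            "q95": float(np.quantile(vals, 0.95)),
            "n_subsets": len(vals),
        })
    return AblationResult(
        subset_scores=dict(subset_scores),
        size_summary=pd.DataFrame(size_rows),
        channel_importance=chan_imp, pair_importance=pair_imp,
        channel_ranks=chan_ranks, pair_ranks=pair_ranks,
    )


def sensor_ablation(sessions: list[SessionData], channel_pool,
                    config: ProtocolConfig,
                    min_subset_size: int | None = None) -> AblationResult:
    """In-session accuracy for every channel subset of a pool.

    Correlation graphs need at least two channels, so TSG-containing
    feature sets use subsets of size >= 2 (BF admits singletons).  Scores
    default to standard accuracy at an 80/20 split.
    """
    tsg_used = "tsg" in config.feature_set
    floor = 2 if tsg_used else 1
    if min_subset_size is None:
        min_subset_size = floor
    if min_subset_size < floor and tsg_used:
        raise ValueError("TSG features need channel subsets of size >= 2")
    n_c = sessions[0].n_channels
    pool = [int(c) for c in channel_pool]
    if any(not 0 <= c < n_c for c in pool):
        raise ValueError(f"channel_pool indices must lie in [0, {n_c})")
    if config.metric == "balanced":
        config = replace(config, metric="standard")
    caches = [_SessionCache(s, config.scheme) for s in sessions]
    scores = {}
    for subset in ablation_subsets(pool, min_subset_size):
        restricted = [c.restrict(subset) for c in caches]
        res = in_session(sessions, config, _caches=restricted)
        scores[subset] = float(res.records["score"].mean())
    return channel_importance(scores)


def summarize_table(results: dict[str, ExperimentResult],
                    percent: bool = True) -> pd.DataFrame:
    """Grid of ``mean (se)`` cells, rows = result labels, cols = settings.

    Missing cells are reported as "n/a".  Scores are printed on the 0-100
    scale by default, matching how such summaries are usually tabulated.
    """
    settings: list = []
    for res in results.values():
        for s in sorted(res.records["setting"].unique()):
            if s not in settings:
                settings.append(s)
    scale = 100.0 if percent else 1.0
    digits = 1 if percent else 3
    table = {}
    for label, res in results.items():
        row = {}
        for s in settings:
            sub = res.records[res.records["setting"] == s]
            if sub.empty:
                row[s] = "n/a"
            else:
                row[s] = (f"{scale * res.cohort_mean(s):.{digits}f} "
                          f"({scale * res.cohort_se(s):.{digits}f})")
        table[label] = row
    return pd.DataFrame(table).T
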