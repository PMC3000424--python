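import itertools

import numpy as np
import pytest

from peploc import features as F
from peploc import model as M
from peploc import sequence_io as sio
from peploc import synthetic_data as S
from peploc.sequence_io import PeptideRecord

SMALL_GRID = M.default_grid(log2_c=(1, 7), log2_gamma=(-5, -1))


def _blob_vectors(n_per_class=10, sep=4.0, seed=0):
    """Two Gaussian clouds in 2-D as raw dict vectors."""
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for label, center in (("a", (0.0, 0.0)), ("b", (sep, sep))):
        for _ in range(n_per_class):
            x, y = rng.normal(center, 0.3)
            vectors.append({"x": float(x), "y": float(y)})
            labels.append(label)
    return vectors, labels


# ---------------------------------------------------------------- params/grid

def test_kernel_params_positive():
    with pytest.raises(ValueError):
        M.KernelParams(C=0, gamma=1)
    with pytest.raises(ValueError):
        M.KernelParams(C=1, gamma=-2)


def test_default_grid_shape():
    grid = M.default_grid()
    assert len(grid) == 11 * 10
    assert M.KernelParams(C=2.0 ** -5, gamma=2.0 ** -15) in grid
    assert M.KernelParams(C=2.0 ** 15, gamma=2.0 ** 3) in grid


# ---------------------------------------------------------------- folds

def test_folds_equal_sizes():
    recs = [PeptideRecord(f"r{i}", "MKAV", label="mit") for i in range(100)]
    folds = M.make_folds(recs, 10, seed=0, stratified=False)
    sizes = np.bincount(folds, minlength=10)
    assert list(sizes) == [10] * 10


def test_folds_near_equal_sizes():
    recs = [PeptideRecord(f"r{i}", "MKAV", label="mit") for i in range(95)]
    folds = M.make_folds(recs, 10, seed=0, stratified=False)
    sizes = sorted(np.bincount(folds, minlength=10))
    assert sizes == [9] * 5 + [10] * 5


def test_folds_deterministic():
    recs = [PeptideRecord(f"r{i}", "MKAV", label="mit" if i % 2 else "chl")
            for i in range(40)]
    a = M.make_folds(recs, 10, seed=3)
    b = M.make_folds(recs, 10, seed=3)
    assert np.array_equal(a, b)


def test_folds_stratified_balances_classes():
    recs = ([PeptideRecord(f"a{i}", "MKAV", label="mit") for i in range(30)]
            + [PeptideRecord(f"b{i}", "MKAV", label="chl") for i in range(30)])
    folds = M.make_folds(recs, 10, seed=1, stratified=True)
    for f in range(10):
        labels = [recs[i].label for i in range(60) if folds[i] == f]
        assert labels.count("mit") == 3
        assert labels.count("chl") == 3


def test_folds_too_many_errors():
    recs = [PeptideRecord(f"r{i}", "MKAV", label="mit") for i in range(5)]
    with pytest.raises(ValueError):
        M.make_folds(recs, 10)


# ---------------------------------------------------------------- training

def test_separable_clouds_train_accuracy_100():
    vectors, labels = _blob_vectors()
    model = M.train_svm(vectors, labels, M.KernelParams(C=8, gamma=0.5), seed=0)
    assert M.predict_labels(model, vectors) == labels


def test_duplicated_training_points_same_predictions():
    vectors, labels = _blob_vectors()
    m1 = M.train_svm(vectors, labels, M.KernelParams(C=8, gamma=0.5), seed=0)
    m2 = M.train_svm(vectors * 2, labels * 2, M.KernelParams(C=8, gamma=0.5), seed=0)
    probe, _ = _blob_vectors(n_per_class=5, seed=99)
    assert M.predict_labels(m1, probe) == M.predict_labels(m2, probe)


def test_single_class_errors():
    vectors, _ = _blob_vectors()
    with pytest.raises(ValueError, match="2 classes"):
        M.train_svm(vectors, ["a"] * len(vectors), M.KernelParams(C=1, gamma=1))


def test_mixed_specs_error(small_table):
    v1 = F.kmer_composition("MKAV", sio.UNGROUPED, 1)
    v2 = F.kmer_composition("MKAV", sio.UNGROUPED, 2)
    with pytest.raises(ValueError, match="mix feature specs"):
        M.train_svm([v1, v2], ["a", "b"], M.KernelParams(C=1, gamma=1))


# ---------------------------------------------------------------- prediction

def test_probabilities_sum_to_one():
    vectors, labels = _blob_vectors()
    model = M.train_svm(vectors, labels, M.KernelParams(C=8, gamma=0.5), seed=0)
    p = M.predict_proba(model, {"x": 1.0, "y": 1.0})
    assert sum(p.probs.values()) == pytest.approx(1.0, abs=1e-6)
    assert set(p.probs) == {"a", "b"}


def test_deep_inside_cloud_argmax():
    vectors, labels = _blob_vectors(sep=6.0)
    model = M.train_svm(vectors, labels, M.KernelParams(C=8, gamma=0.5), seed=0)
    assert M.predict_proba(model, {"x": 0.0, "y": 0.0}).argmax == "a"
    assert M.predict_proba(model, {"x": 6.0, "y": 6.0}).argmax == "b"


def test_spec_mismatch_errors(small_table):
    v = F.kmer_composition("MKAVLIMKAV", sio.UNGROUPED, 1)
    w = F.kmer_composition("MKAVLIMKAV", sio.GROUP_C, 1)
    model = M.train_svm([v, v], ["a", "b"], M.KernelParams(C=1, gamma=1))
    with pytest.raises(ValueError, match="feature mismatch"):
        M.predict_proba(model, w)


# ---------------------------------------------------------------- grid search

def _exhaustive_oracle(vectors, labels, inner_folds, grid, seed):
    """Naive double loop over grid points and folds, recomputed independently."""
    results = {}
    for params in grid:
        accs = []
        for f in sorted(set(inner_folds)):
            tr = [i for i, ff in enumerate(inner_folds) if ff != f]
            va = [i for i, ff in enumerate(inner_folds) if ff == f]
            model = M.train_svm([vectors[i] for i in tr], [labels[i] for i in tr],
                                params, seed=seed)
            pred = M.predict_labels(model, [vectors[i] for i in va])
            accs.append(np.mean([p == labels[i] for p, i in zip(pred, va)]) * 100)
        results[params] = float(np.mean(accs))
    best = max(results, key=lambda p: (results[p], -p.C, -p.gamma))
    return best, results


def test_grid_of_one_point():
    vectors, labels = _blob_vectors()
    folds = np.array([i % 3 for i in range(len(labels))])
    grid = [M.KernelParams(C=2, gamma=0.5)]
    best, table = M.grid_search(vectors, labels, folds, grid)
    assert best == grid[0]
    assert set(table) == set(grid)


def test_grid_search_matches_exhaustive_oracle():
    rng = np.random.default_rng(17)
    # 60-record, 3-class toy set with moderate separation
    vectors, labels = [], []
    centers = {"a": (0, 0), "b": (2, 0), "c": (0, 2)}
    for label, center in centers.items():
        for _ in range(20):
            x, y = rng.normal(center, 0.8)
            vectors.append({"x": float(x), "y": float(y)})
            labels.append(label)
    folds = np.array([i % 5 for i in range(60)])
    grid = [M.KernelParams(C=c, gamma=g)
            for c, g in itertools.product((1.0, 16.0), (0.125, 2.0))]
    best, table = M.grid_search(vectors, labels, folds, grid, seed=0)
    oracle_best, oracle_table = _exhaustive_oracle(vectors, labels, folds, grid, seed=0)
    assert best == oracle_best
    for params in grid:
        assert table[params] == pytest.approx(oracle_table[params])


def test_grid_tie_breaks_to_smaller_c():
    # perfectly separable: several grid points reach 100%
    vectors, labels = _blob_vectors(sep=8.0)
    folds = np.array([i % 2 for i in range(len(labels))])
    grid = [M.KernelParams(C=c, gamma=0.5) for c in (1.0, 4.0, 16.0)]
    best, table = M.grid_search(vectors, labels, folds, grid)
    top = max(table.values())
    tied = [p for p in grid if table[p] == top]
    assert best.C == min(p.C for p in tied)


# ---------------------------------------------------------------- nested CV

def _extract_k1(record):
    return F.kmer_composition(record.sequence, sio.UNGROUPED, 1)


def test_nested_deterministic():
    cfg = S.SyntheticConfig(classes=("chl", "mit"), n_per_class=15,
                            signal_strength=1.0, seed=21)
    recs = S.generate_dataset(cfg)
    grid = [M.KernelParams(C=8, gamma=0.5)]
    r1 = M.nested_evaluate(recs, _extract_k1, grid, seed=4, n_outer=3, n_inner=3)
    r2 = M.nested_evaluate(recs, _extract_k1, grid, seed=4, n_outer=3, n_inner=3)
    assert r1.accuracy == r2.accuracy
    assert [f.accuracy for f in r1.per_fold] == [f.accuracy for f in r2.per_fold]


def test_nested_separable_high_accuracy():
    cfg = S.SyntheticConfig(classes=("chl", "cyt", "mit"), n_per_class=15,
                            signal_strength=1.0, seed=6)
    recs = S.generate_dataset(cfg)
    report = M.nested_evaluate(recs, _extract_k1, SMALL_GRID, seed=6,
                               n_outer=5, n_inner=3)
    assert report.accuracy >= 90.0


def test_nested_shuffled_labels_near_chance():
    cfg = S.SyntheticConfig(classes=("chl", "cyt", "mit"), n_per_class=15,
                            signal_strength=1.0, seed=8)
    recs = S.generate_dataset(cfg)
    rng = np.random.default_rng(8)
    labels = [r.label for r in recs]
    rng.shuffle(labels)
    shuffled = [PeptideRecord(r.id, r.sequence, label=l, source=r.source)
                for r, l in zip(recs, labels)]
    report = M.nested_evaluate(shuffled, _extract_k1, SMALL_GRID, seed=8,
                               n_outer=5, n_inner=3)
    assert abs(report.accuracy - 100 / 3) < 20.0


def test_scaler_fitted_per_outer_fold():
    """No leakage: scaling parameters are fitted on training folds only and
    differ across folds on heterogeneous data."""
    vectors, labels = _blob_vectors(n_per_class=20, seed=33)
    fold1 = list(range(0, 10)) + list(range(20, 30))
    fold2 = list(range(10, 20)) + list(range(30, 40))
    m1 = M.train_svm([vectors[i] for i in fold1], [labels[i] for i in fold1],
                     M.KernelParams(C=1, gamma=1))
    m2 = M.train_svm([vectors[i] for i in fold2], [labels[i] for i in fold2],
                     M.KernelParams(C=1, gamma=1))
    assert not np.allclose(m1.scaler.data_min_, m2.scaler.data_min_)


def test_unlabeled_records_rejected():
    recs = [PeptideRecord(f"r{i}", "MKAVLI" * 10) for i in range(20)]
    with pytest.raises(ValueError, match="label"):
        M.nested_evaluate(recs, _extract_k1, [M.KernelParams(C=1, gamma=1)], seed=0,
                          n_outer=2, n_inner=2)


# ---------------------------------------------------------------- serialization

def test_model_roundtrip(tmp_path):
    vectors, labels = _blob_vectors()
    model = M.train_svm(vectors, labels, M.KernelParams(C=8, gamma=0.5), seed=0)
    path = tmp_path / "model.joblib"
    M.save_model(model, path)
    loaded = M.load_model(path)
    assert loaded.classes == model.classes
    assert loaded.params == model.params
    probe, _ = _blob_vectors(n_per_class=5, seed=77)
    assert M.predict_labels(loaded, probe) == M.predict_labels(model, probe)
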