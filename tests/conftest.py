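import numpy as np
import pytest

import edadrive as ed


@pytest.fixture(scope="session")
def default_fs() -> float:
    return 50.0


@pytest.fixture(scope="session")
def noiseless_text_decomposition():
    """A noiseless text-condition recording, preprocessed and decomposed."""
    cfg = ed.SynthConfig(seed=3, noise_sd=0.0)
    rec, truth = ed.synthesize_recording(cfg, ed.DEFAULT_PROFILES["text"])
    clean = ed.preprocess(rec)
    return rec, truth, clean, ed.decompose(clean)


@pytest.fixture(scope="session")
def pipeline_result_small():
    """End-to-end result on a 3-subject cohort (shared across tests)."""
    return ed.run_pipeline(ed.PipelineConfig(n_subjects=3, seed=7))


def peak_scan_oracle(p, threshold):
    """Literal loop implementation of the slope/curvature peak scan,
    independent of the vectorized one in the package."""
    n = len(p)
    q2 = {}
    for i in range(2, n - 2):
        q0 = abs(p[i + 1] - p[i - 1])
        q1 = abs(p[i + 2] - 2 * p[i] + p[i - 2])
        q2[i] = 1.3 * q0 + 1.1 * q1

    def run_amplitude(run):
        j = run[-1] + 1
        while j < n and p[j] >= p[j - 1]:
            j += 1
        return max(p[i] for i in range(run[0], j))

    peaks, amps = 0, []
    run = []
    for i in range(2, n - 2):
        if q2[i] >= threshold:
            run.append(i)
        elif run:
            peaks += 1
            amps.append(run_amplitude(run))
            run = []
    if run:
        peaks += 1
        amps.append(run_amplitude(run))
    return peaks, sum(amps)


def rfe_algorithm_oracle(X, y, C=1.0):
    """Literal backward-elimination loop computing the weight vector from
    the SVM dual coefficients (w = sum_j alpha_j y_j x_j)."""
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    Xs = StandardScaler().fit_transform(X)
    remaining = list(range(X.shape[1]))
    ranked = []
    while len(remaining) > 1:
        svc = SVC(kernel="linear", C=C).fit(Xs[:, remaining], y)
        w = svc.dual_coef_ @ svc.support_vectors_
        crit = np.ravel(np.asarray(w)) ** 2
        ranked.append(remaining.pop(int(np.argmin(crit))))
    ranked.append(remaining[0])
    return ranked[::-1]


PLANTED_FEATURES = (6, 9, 13, 14, 15, 17, 18)


def planted_cohort(seed, n_subjects=8, n_windows=500, tau=0.05,
                   strengths=(2.0, 1.8, 1.6, 1.4, 1.25, 1.1, 1.0)):
    """Feature table with 7 informative (graded effect sizes) + 11 noise
    columns.  Subjects share a common population sample perturbed per
    subject (mixing weight ``tau``): the per-position-mode consensus rule
    presumes strong cross-subject rank concordance, which fully
    independent subject draws cannot provide."""
    import pandas as pd

    from edadrive.features import FEATURE_NAMES

    rng = np.random.default_rng(seed)
    frames = []
    base = {c: rng.normal(size=(n_windows, 18)) for c in ("normal", "phone")}
    for s in range(n_subjects):
        for cond in ("normal", "phone"):
            X = (np.sqrt(1 - tau**2) * base[cond]
                 + tau * rng.normal(size=(n_windows, 18)))
            if cond != "normal":
                for f, st in zip(PLANTED_FEATURES, strengths):
                    X[:, f - 1] += st
            df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
            df["subject_id"] = f"s{s:02d}"
            df["condition"] = cond
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def smoothed_truth_train(truth, n: int, fs: float, sigma_s: float = 0.2):
    """Ground-truth impulse train on the working grid, Gaussian-smoothed."""
    from scipy.ndimage import gaussian_filter1d

    train = np.zeros(n)
    idx = np.minimum(np.round(np.asarray(truth.impulse_times) * fs).astype(int),
                     n - 1)
    np.add.at(train, idx, np.asarray(truth.impulse_amps) * fs)
    return gaussian_filter1d(train, sigma_s * fs)
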