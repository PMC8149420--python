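"""Pixel-wise tissue classification of a registered CT + histology pair.

After registration every pixel carries four values — the CT grey level and
the three histology colour components — forming a 4D feature space.  A
K-component Gaussian mixture (default K = 6) is fitted to the masked pixels
by expectation maximisation; the per-component posterior probabilities form
one probability map per tissue class, and the mixture weights ("mix
coefficients") estimate each class's pixel fraction.  The mapping from
components to tissue names (tumour cells, vessels/holes, fibres,
nanoparticles, fat, membranes) is observer knowledge supplied by the user,
not inferred by the model.

Features are z-scored before fitting; the EM itself is delegated to
scikit-learn's :class:`~sklearn.mixture.GaussianMixture`, driven one
iteration at a time so the log-likelihood trace is recorded and its
monotonicity checked on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .core_imaging import DegenerateInputError, ParameterError, RasterImage

__all__ = [
    "FeatureImage",
    "MixtureModel",
    "PosteriorMaps",
    "build_features",
    "fit_gmm_em",
    "posterior_maps",
    "report_mix_coefficients",
]


@dataclass
class FeatureImage:
    """Standardised per-pixel feature vectors with their valid-pixel mask.

    ``features`` has shape (H, W, F); ``means``/``scales`` hold the
    per-feature standardisation parameters so raw values can be recovered.
    """

    features: np.ndarray
    mask: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    def masked_matrix(self) -> np.ndarray:
        return self.features[self.mask]

    def inverse_transform(self, standardised: np.ndarray) -> np.ndarray:
        return standardised * self.scales + self.means


@dataclass
class MixtureModel:
    """A fitted K-component multivariate Gaussian mixture."""

    k: int
    means: np.ndarray            # (K, F) in standardised feature space
    covariances: np.ndarray      # (K, F, F)
    mix_coefficients: np.ndarray  # (K,), sums to 1
    log_likelihood_trace: list[float]
    seed: int
    converged: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.mix_coefficients, dtype=np.float64)
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("mix coefficients must be non-negative and sum to 1")

    def to_text(self) -> str:
        lines = [f"k = {self.k}", f"seed = {self.seed}", f"converged = {self.converged}"]
        lines.append("mix_coefficients = " + " ".join(repr(float(v)) for v in self.mix_coefficients))
        for j in range(self.k):
            lines.append(f"mean_{j} = " + " ".join(repr(float(v)) for v in self.means[j]))
            lines.append(
                f"covariance_{j} = " + " ".join(repr(float(v)) for v in self.covariances[j].ravel())
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MixtureModel":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        k = int(kv["k"])
        weights = np.array([float(tok) for tok in kv["mix_coefficients"].split()])
        means = np.array([[float(tok) for tok in kv[f"mean_{j}"].split()] for j in range(k)])
        f = means.shape[1]
        covs = np.array(
            [[float(tok) for tok in kv[f"covariance_{j}"].split()] for j in range(k)]
        ).reshape(k, f, f)
        return cls(k, means, covs, weights, [], int(kv.get("seed", 0)), kv.get("converged") == "True")


@dataclass
class PosteriorMaps:
    """Per-component posterior probability images (zero off-mask)."""

    maps: np.ndarray  # (K, H, W) in [0, 1]
    mask: np.ndarray

    def argmax_labels(self) -> np.ndarray:
        """Hard classification map; off-mask pixels get label -1."""
        labels = np.argmax(self.maps, axis=0).astype(np.int32)
        labels[~self.mask] = -1
        return labels


def build_features(
    ct: RasterImage,
    hist: RasterImage,
    mask: np.ndarray | None = None,
) -> FeatureImage:
    """Stack CT grey + histology RGB into a standardised 4D feature image.

    Each feature is z-scored over the masked pixels; a zero-variance
    feature keeps scale 1 so standardisation stays invertible.
    """
    if ct.n_channels != 1:
        raise ParameterError("CT input must be single-channel")
    if (ct.height, ct.width) != (hist.height, hist.width):
        raise ParameterError("CT and histology must be registered to the same dimensions")
    if mask is None:
        mask = np.ones((ct.height, ct.width), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ct.height, ct.width):
            raise ParameterError("mask dimensions must match the images")
    if not mask.any():
        raise DegenerateInputError("empty mask")
    raw = np.concatenate([ct.pixels, hist.pixels], axis=2)
    sel = raw[mask]
    means = sel.mean(axis=0)
    scales = sel.std(axis=0)
    scales = np.where(scales > 1e-12, scales, 1.0)  # zero-variance feature: scale floored at 1
    features = (raw - means) / scales
    names = ("ct_grey",) + tuple(f"hist_{n}" for n in hist.channel_names)
    return FeatureImage(features, mask, means, scales, names)


def _em_run(
    x: np.ndarray, k: int, init_seed: int, max_iter: int, tol: float
) -> tuple[GaussianMixture, list[float], bool]:
    """One warm-started EM run, one iteration per step, with its trace."""
    n = x.shape[0]
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=1e-6,
        max_iter=1,
        n_init=1,
        init_params="k-means++",
        random_state=int(init_seed),
        warm_start=True,
        tol=0.0,
    )
    rng = np.random.default_rng(init_seed)
    trace: list[float] = []
    reseeded = False
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-iteration fits always "fail to converge"
        for _ in range(max_iter):
            gm.fit(x)
            ll = float(gm.lower_bound_)  # mean per-sample log-likelihood after this E-M step
            if np.any(gm.weights_ < 1e-6):
                if reseeded:
                    raise DegenerateInputError("mixture component collapsed twice")
                reseeded = True
                dead = np.flatnonzero(gm.weights_ < 1e-6)
                for j in dead:
                    gm.means_[j] = x[rng.integers(0, n)]
                    gm.covariances_[j] = np.cov(x.T) + 1e-6 * np.eye(x.shape[1])
                gm.weights_[dead] = 1.0 / k
                gm.weights_ /= gm.weights_.sum()
                gm.precisions_cholesky_ = _prec_chol(gm.covariances_)
                trace.append(ll)
                continue
            if trace and ll - trace[-1] < tol:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
    return gm, trace, converged


def fit_gmm_em(
    features: FeatureImage | np.ndarray,
    k: int = 6,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    n_init: int = 3,
) -> MixtureModel:
    """Fit a full-covariance Gaussian mixture by EM.

    Initialisation is k-means++ seeding; ``n_init`` independent seeded
    starts are run and the one with the best final log-likelihood kept (EM
    is a local optimiser, and a single unlucky seeding can merge two
    clusters).  Everything is deterministic given ``seed``.  Covariances
    carry a 1e-6 diagonal regularisation floor.  EM runs one iteration per
    step so the per-iteration total log-likelihood is recorded; a run stops
    once the gain drops below ``tol`` (per sample) or ``max_iter`` is
    reached.  A collapsing component (weight < 1e-6) is re-seeded once per
    run; a second collapse raises.
    """
    x = features.masked_matrix() if isinstance(features, FeatureImage) else np.asarray(features)
    n = x.shape[0]
    if n < 10 * k:
        raise DegenerateInputError(f"need at least {10 * k} samples to fit {k} components")
    best: tuple[GaussianMixture, list[float], bool] | None = None
    for j in range(max(1, n_init)):
        run = _em_run(x, k, int(seed) + 7919 * j, max_iter, tol)
        if best is None or run[1][-1] > best[1][-1]:
            best = run
    gm, trace, converged = best
    return MixtureModel(
        k=k,
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        mix_coefficients=gm.weights_.copy(),
        log_likelihood_trace=[v * n for v in trace],
        seed=int(seed),
        converged=converged,
    )


def _prec_chol(covariances: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    out = np.empty_like(covariances)
    for j, cov in enumerate(covariances):
        chol = np.linalg.cholesky(cov)
        out[j] = solve_triangular(chol, np.eye(cov.shape[0]), lower=True).T
    return out


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    f = mean.size
    diff = x - mean
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (f * np.log(2.0 * np.pi) + logdet + maha)


def posterior_maps(model: MixtureModel, features: FeatureImage) -> PosteriorMaps:
    """Per-pixel component posteriors by Bayes' rule; off-mask pixels are 0."""
    if model.means.shape[1] != features.n_features:
        raise ParameterError(
            f"model dimensionality {model.means.shape[1]} != feature count {features.n_features}"
        )
    x = features.masked_matrix()
    logp = np.stack(
        [
            np.log(max(model.mix_coefficients[j], 1e-300)) + _log_gauss(x, model.means[j], model.covariances[j])
            for j in range(model.k)
        ]
    )
    logp -= logp.max(axis=0, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=0, keepdims=True)
    h, w = features.mask.shape
    maps = np.zeros((model.k, h, w))
    for j in range(model.k):
        maps[j][features.mask] = p[j]
    return PosteriorMaps(maps, features.mask)


def report_mix_coefficients(
    model: MixtureModel, labels: dict[int, str] | None = None
) -> list[tuple[str, float]]:
    """Components sorted by descending mix coefficient, as percentages.

    ``labels`` optionally maps component indices to tissue names; unlabelled
    components are reported as ``component <j>``.
    """
    order = np.argsort(-model.mix_coefficients, kind="stable")
    out = []
    for j in order:
        name = (labels or {}).get(int(j), f"component {int(j)}")
        out.append((name, float(model.mix_coefficients[j] * 100.0)))
    return out


def format_mix_table(report: list[tuple[str, float]]) -> str:
    lines = ["component\tmix_coefficient_percent"]
    lines += [f"{name}\t{pct:.1f}" for name, pct in report]
    return "\n".join(lines) + "\n"
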