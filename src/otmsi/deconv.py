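"""Optimal-transport linear deconvolution of centroided spectra.

An experimental spectrum, normalized to unit total intensity, is explained as
a nonnegative combination of theoretical isotopic envelopes via a transport
linear program.  Experimental intensity may be moved to a theoretical peak at
cost |Δm/z| per unit, discarded at cost ``kappa_mixture`` per unit, and each
envelope may discard part of its own (scaled) intensity at cost
``kappa_components`` per unit.  The two κ parameters act as soft m/z matching
windows: signal farther than the κ budget from any envelope peak is cheaper
to discard than to transport, so whole envelopes compete for nearby
experimental mass and overlapping envelopes are separated jointly.

The LP (variables: transport plan γ_{ij} >= 0, experimental trash e_i >= 0,
per-envelope trash t_{cj} >= 0, envelope scales p_c >= 0)::

    minimize    Σ γ_{ij} |mz_i - mz_j|  +  κ_mix Σ e_i  +  κ_comp Σ t_{cj}
    subject to  Σ_j γ_{ij} + e_i            = a_i          (each experimental peak)
                Σ_i γ_{i,cj} + t_{cj}       = p_c μ_{cj}   (each envelope peak)

The reported proportion of envelope c is the experimental mass actually
transported to it, so proportions plus the discarded experimental fraction
sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import TheoreticalSpectrum
from .spectra import MSIDataset, Spectrum

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "IonImage",
    "WassersteinDeconvolver",
    "ot_distance",
    "fit_proportions",
    "deconvolve_dataset",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    """κ penalties in Da per unit of discarded intensity."""

    kappa_mixture: float = 0.012
    kappa_components: float = 0.016

    def __post_init__(self) -> None:
        if self.kappa_mixture <= 0 or self.kappa_components <= 0:
            raise ValueError("kappa penalties must be positive")


@dataclass
class DeconvolutionResult:
    """Per-component proportions for one spectrum.

    ``proportions[c]`` is the fraction of the unit-normalized experimental
    intensity transported to component c; ``scales[c]`` is the raw envelope
    scale coefficient (transported mass plus the envelope's own discarded
    intensity).  ``degenerate`` flags an empty/zero-intensity input.
    """

    proportions: np.ndarray
    unexplained_experimental: float
    transport_cost: float
    objective: float = 0.0
    scales: np.ndarray | None = None
    degenerate: bool = False


@dataclass
class IonImage:
    """Per-pixel scalar intensity of one ion on the acquisition grid."""

    values: np.ndarray  # (height, width)
    label: str = ""
    mask: np.ndarray | None = None  # True where a pixel was measured

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)

    @property
    def flat_valid(self) -> np.ndarray:
        return self.values[self.mask]


def ot_distance(a: Spectrum, b: Spectrum) -> float:
    """First Wasserstein distance between two unit-intensity centroid spectra.

    Computed in closed form on the line as the integral of |CDF_a - CDF_b|
    over m/z.
    """
    for s in (a, b):
        if len(s) == 0 or s.total_intensity <= 0:
            raise ValueError("ot_distance requires nonempty spectra")
    wa = a.intensity / a.total_intensity
    wb = b.intensity / b.total_intensity
    mz = np.concatenate([a.mz, b.mz])
    w = np.concatenate([wa, -wb])
    order = np.argsort(mz, kind="stable")
    mz, w = mz[order], w[order]
    cdf_diff = np.cumsum(w)[:-1]
    return float(np.sum(np.abs(cdf_diff) * np.diff(mz)))


def _lp_matrices(exp_mz, exp_int, components, cfg):
    """Build the sparse transport LP; returns (c, A_eq, b_eq, index maps)."""
    comp_mz = np.concatenate([c.mz for c in components])
    comp_p = np.concatenate([c.intensity for c in components])
    comp_id = np.concatenate(
        [np.full(len(c.mz), k) for k, c in enumerate(components)]
    )
    n_exp, n_theo, n_comp = len(exp_mz), len(comp_mz), len(components)

    # pairs farther apart than κ_mix + κ_comp can never beat the two trash
    # routes, so they are pruned without changing the optimum
    dist = np.abs(exp_mz[:, None] - comp_mz[None, :])
    pair_i, pair_j = np.nonzero(dist <= cfg.kappa_mixture + cfg.kappa_components)
    n_pairs = pair_i.size

    # variable layout: [γ pairs | e_i | t_cj | p_c]
    n_var = n_pairs + n_exp + n_theo + n_comp
    cost = np.concatenate(
        [
            dist[pair_i, pair_j],
            np.full(n_exp, cfg.kappa_mixture),
            np.full(n_theo, cfg.kappa_components),
            np.zeros(n_comp),
        ]
    )

    rows, cols, vals = [], [], []
    # experimental balance rows 0..n_exp-1
    rows.extend(pair_i)
    cols.extend(range(n_pairs))
    vals.extend(np.ones(n_pairs))
    rows.extend(range(n_exp))
    cols.extend(range(n_pairs, n_pairs + n_exp))
    vals.extend(np.ones(n_exp))
    # theoretical balance rows n_exp..n_exp+n_theo-1
    rows.extend(n_exp + pair_j)
    cols.extend(range(n_pairs))
    vals.extend(np.ones(n_pairs))
    rows.extend(n_exp + np.arange(n_theo))
    cols.extend(range(n_pairs + n_exp, n_pairs + n_exp + n_theo))
    vals.extend(np.ones(n_theo))
    rows.extend(n_exp + np.arange(n_theo))
    cols.extend(n_pairs + n_exp + n_theo + comp_id)
    vals.extend(-comp_p)

    A_eq = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_exp + n_theo, n_var)
    )
    b_eq = np.concatenate([exp_int, np.zeros(n_theo)])
    return cost, A_eq, b_eq, (n_pairs, n_exp, n_theo, n_comp, pair_i, pair_j, comp_id)


def fit_proportions(
    experimental: Spectrum,
    components: list[TheoreticalSpectrum],
    cfg: DeconvolutionConfig,
) -> DeconvolutionResult:
    """Fit theoretical envelopes to one centroided spectrum by the transport LP.

    The experimental spectrum must be normalized to unit total intensity
    (tolerance 1e-6); an empty or zero-intensity spectrum yields an all-zero
    result flagged ``degenerate`` rather than an exception, so whole-dataset
    runs never abort.
    """
    if not components:
        raise ValueError("components must be nonempty")
    k = len(components)
    if len(experimental) == 0 or experimental.total_intensity <= 0:
        return DeconvolutionResult(
            np.zeros(k), 0.0, 0.0, 0.0, np.zeros(k), degenerate=True
        )
    total = experimental.total_intensity
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            "experimental spectrum must be normalized to unit total intensity"
        )
    for comp in components:
        if abs(comp.intensity.sum() - 1.0) > 1e-6:
            raise ValueError(f"component {comp.label!r} is not normalized")

    cost, A_eq, b_eq, layout = _lp_matrices(
        experimental.mz, experimental.intensity, components, cfg
    )
    n_pairs, n_exp, n_theo, n_comp, pair_i, pair_j, comp_id = layout
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - trash variables keep the LP feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    x = res.x
    gamma = x[:n_pairs]
    trash_exp = x[n_pairs : n_pairs + n_exp]
    scales = x[n_pairs + n_exp + n_theo :]

    transported = np.zeros(n_comp)
    np.add.at(transported, comp_id[pair_j], gamma)
    transport_cost = float((gamma * cost[:n_pairs]).sum())
    return DeconvolutionResult(
        proportions=transported,
        unexplained_experimental=float(trash_exp.sum()),
        transport_cost=transport_cost,
        objective=float(res.fun),
        scales=scales,
    )


class WassersteinDeconvolver(TransformerMixin, BaseEstimator):
    """Transform centroided spectra into per-ion signal proportions.

    Parameters
    ----------
    components : list of TheoreticalSpectrum
        Reference envelopes (each normalized to unit intensity).
    kappa_mixture, kappa_components : float
        Penalties in Da for discarding experimental / theoretical intensity.

    After ``fit``, ``transform(spectra)`` returns an (n_spectra, n_components
    + 1) array whose last column is the unexplained experimental fraction;
    rows sum to 1 for non-degenerate spectra.
    """

    def __init__(
        self,
        components: list[TheoreticalSpectrum] | None = None,
        kappa_mixture: float = 0.012,
        kappa_components: float = 0.016,
    ):
        self.components = components
        self.kappa_mixture = kappa_mixture
        self.kappa_components = kappa_components

    def fit(self, X=None, y=None) -> "WassersteinDeconvolver":
        if not self.components:
            raise ValueError("components must be provided")
        self.config_ = DeconvolutionConfig(self.kappa_mixture, self.kappa_components)
        self.components_ = list(self.components)
        self.labels_ = [c.label for c in self.components_]
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "components_")
        spectra = [s for _, _, s in X.pixels] if isinstance(X, MSIDataset) else X
        out = np.empty((len(spectra), len(self.components_) + 1))
        for i, s in enumerate(spectra):
            total = s.total_intensity if len(s) else 0.0
            normalized = s.scaled(1.0 / total) if total > 0 else s
            r = fit_proportions(normalized, self.components_, self.config_)
            out[i, :-1] = r.proportions
            out[i, -1] = r.unexplained_experimental
        return out


def deconvolve_dataset(
    ds: MSIDataset,
    components: list[TheoreticalSpectrum],
    cfg: DeconvolutionConfig,
    scale: str = "tic",
) -> dict[str, IonImage]:
    """Fit envelopes to every pixel independently and assemble ion images.

    ``scale="tic"`` (default) multiplies each pixel's proportions by its total
    centroided intensity, yielding the estimated per-ion signal; for
    TIC-normalized data this differs from ``scale="proportion"`` only by a
    constant factor.  Pixels with zero intensity are flagged in the image
    masks and carry all-zero values.  Results are independent of pixel order.
    """
    if scale not in ("tic", "proportion"):
        raise ValueError("scale must be 'tic' or 'proportion'")
    dec = WassersteinDeconvolver(
        components, cfg.kappa_mixture, cfg.kappa_components
    ).fit()
    props = dec.transform(ds)
    tics = np.array([s.total_intensity for _, _, s in ds.pixels])
    values = props * tics[:, None] if scale == "tic" else props

    shape = (ds.height, ds.width)
    grids = {
        label: np.zeros(shape) for label in dec.labels_ + ["unexplained"]
    }
    measured = np.zeros(shape, dtype=bool)
    nonzero = np.zeros(shape, dtype=bool)
    for i, (x, y, _) in enumerate(ds.pixels):
        measured[y, x] = True
        for j, label in enumerate(dec.labels_):
            grids[label][y, x] = values[i, j]
        grids["unexplained"][y, x] = values[i, -1]
        nonzero[y, x] = tics[i] > 0
    return {
        label: IonImage(grid, label, mask=measured & nonzero)
        for label, grid in grids.items()
    }
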