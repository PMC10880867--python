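"""Single-level DWT decomposition and between-group dissimilarity.

Each severity group's mean angle curve is decomposed once with a discrete
wavelet transform into approximation coefficients cA (low-frequency: the
slow trend of the movement — how far and how fast the joint opens over the
whole test) and detail coefficients cD (high-frequency: rapid fluctuations
such as tremor or estimator jitter). Between-group dissimilarity at a site
is then the elementwise absolute difference of the two groups' coefficient
arrays, reduced to one scalar per coefficient type (sum by default).

The default family is the Haar wavelet (the single-vanishing-moment
orthogonal wavelet): for an even-length input it needs no boundary
extension, has the closed form

    cA_k = (x_{2k} + x_{2k+1}) / sqrt(2),   cD_k = (x_{2k} - x_{2k+1}) / sqrt(2),

and conserves energy exactly, which makes every downstream number auditable.
Any PyWavelets discrete family may be substituted; the family used is
recorded on every result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import pywt

from .errors import ComparisonError, ConfigurationError

__all__ = [
    "WaveletDecomposition",
    "GroupComparisonResult",
    "dwt_single_level",
    "inverse_dwt",
    "coefficient_difference",
    "compare_groups",
    "comparison_table",
    "plot_report",
]

DEFAULT_WAVELET = "haar"
Aggregation = Literal["sum", "mean", "max"]
_AGG_FUNCS = {"sum": np.sum, "mean": np.mean, "max": np.max}


@dataclass
class WaveletDecomposition:
    """Single-level DWT of one curve: cA, cD, family, original length."""

    cA: np.ndarray
    cD: np.ndarray
    wavelet: str
    input_length: int

    def __post_init__(self) -> None:
        self.cA = np.asarray(self.cA, dtype=float)
        self.cD = np.asarray(self.cD, dtype=float)


@dataclass
class GroupComparisonResult:
    """Between-group coefficient differences at one site.

    ``dcA``/``dcD`` are the elementwise absolute differences of the two
    groups' approximation/detail coefficients; ``agg_cA``/``agg_cD`` reduce
    them to one scalar each with the declared aggregation. The per-group
    decompositions are retained for plotting.
    """

    site: str
    dcA: np.ndarray
    dcD: np.ndarray
    agg_cA: float
    agg_cD: float
    aggregation: Aggregation
    decompositions: dict[str, WaveletDecomposition] | None = None


def dwt_single_level(x, wavelet: str = DEFAULT_WAVELET) -> WaveletDecomposition:
    """Single-level discrete wavelet transform of a 1-D series.

    With the default Haar family and an even input length the coefficient
    arrays each have exactly half the input length; longer-support families
    use PyWavelets' symmetric boundary extension and are slightly longer.

    Raises
    ------
    ConfigurationError
        Unknown wavelet family.
    ValueError
        Input shorter than 2 samples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("input must be a 1-D series of length >= 2")
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet family {wavelet!r}") from exc
    cA, cD = pywt.dwt(x, wav, mode="symmetric")
    return WaveletDecomposition(cA=cA, cD=cD, wavelet=wavelet, input_length=x.shape[0])


def inverse_dwt(dec: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the original series from a single-level decomposition."""
    rec = pywt.idwt(dec.cA, dec.cD, dec.wavelet, mode="symmetric")
    return rec[: dec.input_length]


def coefficient_difference(
    d1: WaveletDecomposition,
    d2: WaveletDecomposition,
    aggregation: Aggregation = "sum",
    site: str = "",
) -> GroupComparisonResult:
    """Absolute coefficient differences between two decompositions.

    Raises
    ------
    ComparisonError
        Different wavelet families or input lengths.
    """
    if d1.wavelet != d2.wavelet:
        raise ComparisonError(
            f"wavelet mismatch: {d1.wavelet!r} vs {d2.wavelet!r}"
        )
    if d1.input_length != d2.input_length or d1.cA.shape != d2.cA.shape:
        raise ComparisonError(
            f"length mismatch: {d1.input_length} vs {d2.input_length}"
        )
    if aggregation not in _AGG_FUNCS:
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    agg = _AGG_FUNCS[aggregation]
    dcA = np.abs(d1.cA - d2.cA)
    dcD = np.abs(d1.cD - d2.cD)
    return GroupComparisonResult(
        site=site,
        dcA=dcA,
        dcD=dcD,
        agg_cA=float(agg(dcA)),
        agg_cD=float(agg(dcD)),
        aggregation=aggregation,
    )


def compare_groups(
    mean_curves: dict[tuple[str, str], np.ndarray],
    wavelet: str = DEFAULT_WAVELET,
    aggregation: Aggregation = "sum",
    levels: tuple[str, str] = ("mild", "severe"),
) -> dict[str, GroupComparisonResult]:
    """Decompose and difference both severity levels' mean curves per site.

    ``mean_curves`` maps (site, level) -> curve, as produced by
    :func:`sitstand.cohort.group_mean_curves`. Every site must carry both
    levels with curves of equal length.
    """
    sites = sorted({site for site, _ in mean_curves})
    results: dict[str, GroupComparisonResult] = {}
    for site in sites:
        try:
            c1 = mean_curves[(site, levels[0])]
            c2 = mean_curves[(site, levels[1])]
        except KeyError as exc:
            raise ComparisonError(
                f"site {site!r} is missing level {exc.args[0][1]!r}"
            ) from None
        d1 = dwt_single_level(c1, wavelet)
        d2 = dwt_single_level(c2, wavelet)
        result = coefficient_difference(d1, d2, aggregation, site=site)
        result.decompositions = {levels[0]: d1, levels[1]: d2}
        results[site] = result
    return results


def comparison_table(
    comparisons_by_dimension: dict[str, dict[str, GroupComparisonResult]],
) -> pd.DataFrame:
    """Tabulate aggregate differences: rows = sites, columns = (dimension, cA/cD)."""
    sites = sorted(
        {site for comps in comparisons_by_dimension.values() for site in comps}
    )
    data = {}
    for dim, comps in comparisons_by_dimension.items():
        data[(dim, "cA")] = [comps[s].agg_cA if s in comps else np.nan for s in sites]
        data[(dim, "cD")] = [comps[s].agg_cD if s in comps else np.nan for s in sites]
    table = pd.DataFrame(data, index=sites)
    table.index.name = "site"
    return table


def plot_report(
    pools,
    mean_curves: dict[tuple[str, str], np.ndarray],
    comparisons: dict[str, GroupComparisonResult],
    out_dir: str | Path,
) -> list[Path]:
    """Write per-group curve plots and per-site coefficient plots.

    One figure per (site, level) shows every subject curve in the pool with
    the group mean overlaid in red; one figure per site shows both groups'
    cA and cD coefficient arrays. Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for (site, level), mean in sorted(mean_curves.items()):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for curve in pools.pools.get((site, level), []):
            ax.plot(curve.values, color="0.7", lw=0.6, alpha=0.6)
        ax.plot(mean, color="red", lw=1.8, label="group mean")
        ax.set_xlabel("sampling point")
        ax.set_ylabel("angle (deg)")
        ax.set_title(f"{site} — {level} ({pools.dimension})")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        path = out_dir / f"curves_{pools.dimension}_{site}_{level}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    for site, result in sorted(comparisons.items()):
        if not result.decompositions:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for level, dec in result.decompositions.items():
            axes[0].plot(dec.cA, lw=1.0, label=f"cA ({level})")
            axes[1].plot(dec.cD, lw=1.0, label=f"cD ({level})")
        axes[0].set_title(f"{site}: approximation (cA)")
        axes[1].set_title(f"{site}: detail (cD)")
        for ax in axes:
            ax.set_xlabel("coefficient index")
            ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"coefficients_{pools.dimension}_{site}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    return written
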