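"""Markov-chain diagnostics: psrf, effective sample size, sampler comparison.

* :func:`psrf` — Gelman–Rubin potential scale reduction factor,
  ``sqrt(var_plus / W)`` with ``var_plus = (N-1)/N * W + B/N``; values near 1
  indicate between-chain agreement. A split-chain variant (each chain halved)
  is available and labeled in the report.
* :func:`effective_sample_size` — ``M*N / (1 + 2 * sum rho_t)`` with
  autocorrelations combined across chains and truncated by Geyer's
  initial-positive-sequence rule (stop before the first negative sum of an
  even/odd autocorrelation pair).
* :func:`compare_samples` — per-flux rank-based location comparison between
  two archives (Wilcoxon signed-rank on paired thinned draws) with
  Benjamini–Hochberg multiplicity adjustment.

Fluxes with (numerically) zero variance are flagged as constant and excluded
from averages rather than producing divide-by-zero artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, LooplessFluxError

__all__ = [
    "DiagnosticsReport",
    "psrf",
    "effective_sample_size",
    "time_per_effective_sample",
    "compare_samples",
    "diagnose",
]

_CONST_VAR = 1e-14


@dataclass
class DiagnosticsReport:
    """Per-flux convergence diagnostics for one sample archive."""

    psrf: np.ndarray
    n_eff: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # per-flux constant flag (within-chain variance ~ 0)
    rxn_ids: list[str]
    time_per_eff: float | None = None
    split_chains: bool = False
    comparison: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction": self.rxn_ids,
                "psrf": self.psrf,
                "n_eff": self.n_eff,
                "mean": self.mean,
                "sd": self.sd,
                "constant": self.constant,
            }
        )

    def summary(self) -> dict:
        nc = ~self.constant
        return {
            "max_psrf": float(np.max(self.psrf[nc])) if nc.any() else None,
            "mean_n_eff": float(np.mean(self.n_eff[nc])) if nc.any() else None,
            "time_per_eff_s": self.time_per_eff,
            "n_constant_fluxes": int(self.constant.sum()),
            "split_chains": self.split_chains,
        }

    def save(self, directory: str) -> None:
        import json
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "diagnostics.csv", index=False)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump({"summary": self.summary(), "notes": self.notes}, fh, indent=2)
        if self.comparison is not None:
            self.comparison.to_csv(out / "comparison.csv", index=False)


def _as_chains(chains: np.ndarray) -> np.ndarray:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    if chains.ndim != 3:
        raise ValueError("chains must have shape (M, N) or (M, N, F)")
    return chains


def _maybe_split(chains: np.ndarray, split: bool) -> np.ndarray:
    if not split:
        return chains
    M, N, F = chains.shape
    half = N // 2
    return np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)


def psrf(
    chains: np.ndarray, split_chains: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Potential scale reduction factor per flux; returns (psrf, constant_flag).

    ``chains`` has shape (M chains, N draws, F fluxes). For identical chains
    the statistic equals its floor ``sqrt((N-1)/N)``. Fluxes whose pooled
    within-chain variance is below 1e-14 are reported as 1 with the constant
    flag set.
    """
    chains = _maybe_split(_as_chains(chains), split_chains)
    M, N, F = chains.shape
    if M < 2:
        raise LooplessFluxError("psrf needs at least 2 chains")
    if N < 4:
        raise LooplessFluxError("psrf needs at least 4 draws per chain")
    chain_means = chains.mean(axis=1)  # (M, F)
    W = chains.var(axis=1, ddof=1).mean(axis=0)  # (F,)
    B_over_N = chain_means.var(axis=0, ddof=1)  # B/N
    constant = W <= _CONST_VAR
    out = np.ones(F)
    ok = ~constant
    var_plus = (N - 1) / N * W[ok] + B_over_N[ok]
    out[ok] = np.sqrt(var_plus / W[ok])
    return out, constant


def _autocov_fft(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of a 1-D series via FFT (divides by N)."""
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def effective_sample_size(chains: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multi-chain ESS per flux; returns (n_eff, constant_flag).

    Combined autocorrelations (Stan-style): ``rho_t = 1 - (W - mean_c
    acov_{c,t}) / var_plus``, summed under Geyer's initial-positive-sequence
    truncation. Capped at the total draw count M*N; floored at 1 (constant
    fluxes report 1, flagged).
    """
    chains = _as_chains(chains)
    M, N, F = chains.shape
    if M < 2:
        raise LooplessFluxError("effective_sample_size needs at least 2 chains")
    if N < 4:
        raise LooplessFluxError("effective_sample_size needs at least 4 draws")
    n_eff = np.empty(F)
    constant = np.zeros(F, dtype=bool)
    for f in range(F):
        x = chains[:, :, f]
        W = x.var(axis=1, ddof=1).mean()
        if W <= _CONST_VAR:
            n_eff[f] = 1.0
            constant[f] = True
            continue
        B_over_N = x.mean(axis=1).var(ddof=1)
        var_plus = (N - 1) / N * W + B_over_N
        acov = np.mean([_autocov_fft(x[m]) for m in range(M)], axis=0)
        rho = 1.0 - (W - acov) / var_plus  # rho[0] ~ 1 - B/(N*var_plus)
        # Geyer initial positive sequence on pair sums rho_{2k}+rho_{2k+1}
        tau = rho[0]
        t = 1
        while t + 1 < N:
            pair = rho[t] + rho[t + 1]
            if pair <= 0:
                break
            tau += 2 * pair
            t += 2
        n_eff[f] = min(max(M * N / max(tau, 1e-12), 1.0), M * N)
    return n_eff, constant


def time_per_effective_sample(
    wall_time_s: float, n_eff: np.ndarray, constant: np.ndarray
) -> float | None:
    """Runtime divided by the average (over non-constant fluxes) ESS.

    The field's standard cost-per-quality metric for comparing samplers.
    Returns ``None`` when every flux is constant.
    """
    nc = ~np.asarray(constant, dtype=bool)
    if not nc.any():
        return None
    return float(wall_time_s / np.mean(np.asarray(n_eff)[nc]))


def _independence_step(archive) -> int:
    """Subsampling stride that renders stored draws roughly independent.

    The signed-rank test assumes independent pairs; archived MCMC draws are
    autocorrelated, so they are strided down to their effective information
    content (total draws / median ESS) before testing.
    """
    try:
        n_eff, const = effective_sample_size(archive.chains_array)
    except LooplessFluxError:
        return 1
    if np.all(const):
        return 1
    total = len(archive.samples)
    return max(1, int(np.ceil(total / np.median(n_eff[~const]))))


def compare_samples(archive_a, archive_b, subsample: int | None = None) -> pd.DataFrame:
    """Per-flux rank-based comparison of two archives (plus BH adjustment).

    Each flux is tested with the Wilcoxon signed-rank statistic on paired
    draws (archives truncated to the shorter length). Draws are first strided
    down to an approximately independent subset — by ``subsample`` if given,
    otherwise by an ESS-based automatic stride — since the test's nominal
    level holds only for independent pairs. Raw p-values are adjusted across
    fluxes with Benjamini–Hochberg. A flux whose draws are pairwise identical
    reports p = 1. Symmetric in its arguments up to the sign of the deltas.
    """
    if list(archive_a.rxn_ids) != list(archive_b.rxn_ids):
        only_a = set(archive_a.rxn_ids) - set(archive_b.rxn_ids)
        only_b = set(archive_b.rxn_ids) - set(archive_a.rxn_ids)
        raise AlignmentError(
            "archives cover different reaction sets/orderings; "
            f"only in first: {sorted(only_a)}; only in second: {sorted(only_b)}"
        )
    if subsample is None:
        subsample = max(_independence_step(archive_a), _independence_step(archive_b))
    A, B = archive_a.samples[::subsample], archive_b.samples[::subsample]
    L = min(len(A), len(B))
    A, B = A[:L], B[:L]
    F = A.shape[1]
    stat = np.empty(F)
    p_raw = np.empty(F)
    for f in range(F):
        diff = A[:, f] - B[:, f]
        if np.all(diff == 0):
            stat[f], p_raw[f] = 0.0, 1.0
            continue
        res = stats.wilcoxon(diff, zero_method="wilcox")
        stat[f], p_raw[f] = res.statistic, res.pvalue
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    table = pd.DataFrame(
        {
            "reaction": archive_a.rxn_ids,
            "statistic": stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "mean_a": A.mean(axis=0),
            "mean_b": B.mean(axis=0),
            "delta_mean": A.mean(axis=0) - B.mean(axis=0),
            "sd_a": A.std(axis=0, ddof=1),
            "sd_b": B.std(axis=0, ddof=1),
        }
    )
    table.attrs["n_flagged_at_0.05"] = int((p_adj <= 0.05).sum())
    table.attrs["adjustment"] = "benjamini-hochberg"
    table.attrs["test"] = "wilcoxon-signed-rank"
    table.attrs["subsample_step"] = int(subsample)
    table.attrs["n_pairs"] = int(L)
    return table


def diagnose(
    archive, other=None, split_chains: bool = False
) -> DiagnosticsReport:
    """Build a full report from one archive (optionally comparing a second)."""
    chains = archive.chains_array
    r, const_r = psrf(chains, split_chains=split_chains)
    n_eff, const_e = effective_sample_size(chains)
    constant = const_r | const_e
    wall = archive.meta.get("wall_time_s")
    report = DiagnosticsReport(
        psrf=r,
        n_eff=n_eff,
        mean=archive.samples.mean(axis=0),
        sd=archive.samples.std(axis=0, ddof=1),
        constant=constant,
        rxn_ids=list(archive.rxn_ids),
        time_per_eff=(
            None if wall is None else time_per_effective_sample(wall, n_eff, constant)
        ),
        split_chains=split_chains,
    )
    report.notes.append(
        "sign-extraction tolerance tol_zero="
        f"{archive.meta.get('tol_zero')} decides borderline loop verdicts"
    )
    if other is not None:
        report.comparison = compare_samples(archive, other)
    return report
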