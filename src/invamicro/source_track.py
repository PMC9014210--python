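"""Microbial source tracking by a multinomial-mixture EM, in the reciprocal
sink/source design used for host-to-host microbiome attribution.

Each sink community is modelled as a draw

    sink ~ Multinomial(N, sum_j alpha_j * gamma_j)

over candidate source profiles ``gamma_j`` plus an "unknown" source.  Known
source profiles are fixed at their (pseudocount-smoothed) observed
proportions; the unknown profile is re-estimated at every M-step from the
expected counts not attributed to any known source.  The mixing proportions
``alpha`` (which sum to one) are the quantity of interest: the estimated
contribution of each source to the sink.

This is a deliberately simplified variant of FEAST-style estimators, which
jointly re-estimate the known source compositions as well; fixing them
keeps the EM convex in behaviour and easily testable while preserving the
contribution estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountTable
from .multivar_stats import StatTestResult, group_compare

logger = logging.getLogger(__name__)


@dataclass
class SourceEstimate:
    sink_id: str
    source_ids: list[str]
    proportions: np.ndarray        # aligned with source_ids + ['unknown']
    log_likelihood: float
    iterations: int
    seed: int
    #: per-iteration EM objective (data log-likelihood plus the Dirichlet
    #: log-prior on the unknown profile); non-decreasing by construction
    ll_trace: np.ndarray = field(default=None, repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions,
                         index=list(self.source_ids) + ["unknown"],
                         name=self.sink_id)


def estimate_sources(sink_counts: np.ndarray, source_profiles: pd.DataFrame,
                     n_restarts: int = 5, max_iter: int = 2000,
                     tol: float = 1e-8, seed: int = 0,
                     include_unknown: bool = True,
                     smoothing: float = 1e-6,
                     unknown_prior_strength: float = 4.0) -> SourceEstimate:
    """EM fit of source mixing proportions for one sink.

    ``source_profiles`` has one row per source (counts or proportions over
    the same features as ``sink_counts``).  Profiles are smoothed with a
    pseudocount of ``smoothing`` x depth before normalisation so that
    features unseen in a source have small, not zero, probability.

    The unknown-source profile starts uniform and is re-estimated at every
    M-step as a MAP update under a symmetric Dirichlet prior of total
    weight ``unknown_prior_strength`` x sink depth.  A completely free
    unknown profile makes the mixture unidentifiable (setting the unknown
    to the empirical sink distribution is always the global optimum); the
    uniform prior keeps the unknown a residual component that only claims
    counts the known sources cannot explain, while still adapting to
    genuinely novel features.
    """
    x = np.asarray(sink_counts, dtype=float)
    if x.sum() < 1:
        raise ValueError("sink has zero depth")
    s = source_profiles.to_numpy(dtype=float)
    if s.shape[1] != len(x):
        raise ValueError("features of sink and sources are not aligned")
    source_ids = [str(i) for i in source_profiles.index]
    _warn_duplicate_profiles(s, source_ids)
    row_tot = s.sum(axis=1, keepdims=True)
    if (row_tot == 0).any():
        raise ValueError("source with zero total counts")
    gamma_known = (s + smoothing * row_tot) / (row_tot * (1 + smoothing * s.shape[1]))
    gamma_known /= gamma_known.sum(axis=1, keepdims=True)
    n_known = gamma_known.shape[0]
    n_src = n_known + (1 if include_unknown else 0)
    f = len(x)

    lam = unknown_prior_strength * x.sum() / f
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        alpha = np.full(n_src, 1.0 / n_src)
        if restart > 0:
            alpha = rng.dirichlet(np.ones(n_src))
        gamma_u = np.full(f, 1.0 / f) if include_unknown else None
        ll_prev = -np.inf
        trace = []
        for it in range(1, max_iter + 1):
            gamma = (np.vstack([gamma_known, gamma_u])
                     if include_unknown else gamma_known)
            mix = alpha @ gamma                     # per-feature mixture prob
            mix = np.maximum(mix, 1e-300)
            ll = float(x @ np.log(mix))
            if include_unknown:
                ll += float(lam * np.log(np.maximum(gamma_u, 1e-300)).sum())
            trace.append(ll)
            # E-step responsibilities aggregated over features
            resp = alpha[:, None] * gamma / mix[None, :]   # sources x features
            expected = resp * x[None, :]
            alpha = expected.sum(axis=1) / x.sum()
            alpha = np.maximum(alpha, 0)
            alpha /= alpha.sum()
            if include_unknown:
                eu = expected[-1]
                gamma_u = (eu + lam) / (eu.sum() + lam * f)
            if it > 1 and abs(ll - ll_prev) <= tol * max(abs(ll_prev), 1.0):
                break
            ll_prev = ll
        if best is None or ll > best.log_likelihood:
            props = alpha if include_unknown else np.append(alpha, 0.0)
            best = SourceEstimate("", source_ids, props, ll, it, seed,
                                  ll_trace=np.array(trace))
    return best


def _warn_duplicate_profiles(s: np.ndarray, ids: list[str]) -> None:
    norm = s / np.maximum(s.sum(axis=1, keepdims=True), 1e-300)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.allclose(norm[i], norm[j]):
                warnings.warn(
                    f"identical source profiles {ids[i]!r} and {ids[j]!r}: "
                    "their individual proportions are not identifiable "
                    "(their sum is)", stacklevel=3)
                return


# ---------------------------------------------------------------------------
# Reciprocal study design
# ---------------------------------------------------------------------------

@dataclass
class SinkTask:
    sink_id: str
    source_ids: list[str]
    site: str
    direction: str


def reciprocal_design(table: CountTable, direction: str) -> list[SinkTask]:
    """Enumerate sink/source tasks for one attribution direction.

    ``direction='native_sink'``: every native-mussel specimen is a sink and
    all co-occurring (same-site) specimens of other species -- other native
    mussels, invasive hosts, seston, sediment -- are its sources.
    ``direction='invasive_sink'``: every invasive specimen is a sink with
    co-occurring native mussels, seston and sediment as sources.  A specimen
    never appears in its own source set.
    """
    if direction not in ("native_sink", "invasive_sink"):
        raise ValueError(f"unknown direction {direction!r}")
    md = table.metadata
    tasks = []
    sink_type = "native_mussel" if direction == "native_sink" else "invasive"
    for sid in table.sample_ids:
        if md.at[sid, "host_type"] != sink_type:
            continue
        site = md.at[sid, "site"]
        same_site = md.index[(md["site"] == site) & (md.index != sid)]
        if direction == "native_sink":
            sources = [s for s in same_site
                       if md.at[s, "host_type"] in
                       ("native_mussel", "invasive", "seston", "sediment")
                       and md.at[s, "host_species"] != md.at[sid,
                                                            "host_species"]]
        else:
            sources = [s for s in same_site
                       if md.at[s, "host_type"] in
                       ("native_mussel", "seston", "sediment")]
        if not sources:
            logger.warning("sink %s has no co-occurring sources; skipped", sid)
            continue
        tasks.append(SinkTask(sid, sources, site, direction))
    return tasks


def run_design(table: CountTable, direction: str, n_restarts: int = 5,
               seed: int = 0, **em_kwargs) -> list[SourceEstimate]:
    """Run the EM on every sink task of one direction."""
    tasks = reciprocal_design(table, direction)
    estimates = []
    rng = np.random.default_rng(seed)
    for task in tasks:
        est = estimate_sources(
            table.counts.loc[task.sink_id].to_numpy(),
            table.counts.loc[task.source_ids],
            n_restarts=n_restarts, seed=int(rng.integers(2 ** 31)),
            **em_kwargs)
        est.sink_id = task.sink_id
        estimates.append(est)
    return estimates


def aggregate_contributions(estimates: list[SourceEstimate],
                            table: CountTable,
                            grouping: str = "recipient_species",
                            focal_host_type: str | None = None
                            ) -> tuple[pd.DataFrame, StatTestResult]:
    """Mean +/- SD of source contributions per group, with a Kruskal-Wallis
    test across groups.

    The per-sink focal contribution is the summed proportion attributed to
    sources of ``focal_host_type`` (default: invasive hosts for native
    sinks, native mussels for invasive sinks).  ``grouping`` is one of
    ``recipient_species``, ``source_species`` or ``site``.
    """
    if not estimates:
        raise ValueError("no source estimates to aggregate")
    md = table.metadata
    rows = []
    for est in estimates:
        sink_type = md.at[est.sink_id, "host_type"]
        focal = focal_host_type or (
            "invasive" if sink_type == "native_mussel" else "native_mussel")
        ser = est.as_series()
        by_species: dict[str, float] = {}
        for src, a in ser.items():
            if src == "unknown":
                continue
            if md.at[src, "host_type"] != focal:
                continue
            sp = md.at[src, "host_species"]
            by_species[sp] = by_species.get(sp, 0.0) + float(a)
        total = sum(by_species.values())
        base = {"sink_id": est.sink_id,
                "recipient_species": md.at[est.sink_id, "host_species"],
                "site": md.at[est.sink_id, "site"],
                "focal_contribution": total}
        if grouping == "source_species":
            for sp, a in by_species.items():
                rows.append({**base, "source_species": sp, "contribution": a})
        else:
            rows.append({**base, "contribution": total})
    df = pd.DataFrame(rows)
    key = {"recipient_species": "recipient_species",
           "source_species": "source_species", "site": "site"}[grouping]
    summary = df.groupby(key)["contribution"].agg(["mean", "std", "count"])
    if df[key].nunique() < 2:
        raise ValueError("need >= 2 groups for the Kruskal-Wallis comparison")
    kw = group_compare(df["contribution"].to_numpy(), df[key].to_numpy(),
                       test="kruskal_wallis")
    return summary, kw
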