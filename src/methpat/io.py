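"""Plain-text table formats and the estimate/simulate/evaluate workflows.

All files are tab-separated text.  Count tables have a ``pattern<TAB>count``
header, one binary pattern string and a non-negative integer count per row;
distribution tables are the same with probabilities in place of counts.
Lines beginning with ``#`` are comments and are ignored on input; the
workflows write their parameter echo as such comment lines so every output
records how to reproduce it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .error_model import ErrorModel, PatternDistribution
from .estimator import EstimationResult, estimate_fast, estimate_slow, naive_estimate
from .evaluate import tpr_fpr_curve
from .patterns import PatternCounts, encode_pattern
from .simulate import SimulationSpec, simulate_counts

__all__ = [
    "read_counts",
    "write_counts",
    "read_distribution_table",
    "write_distribution_table",
    "write_estimate",
    "run_estimate",
    "run_simulate",
    "run_evaluate",
]

logger = logging.getLogger("methpat")


class FormatError(ValueError):
    """Malformed input table; the message names the offending line."""


def _read_table(path) -> list[tuple[int, str, str]]:
    """Non-comment data rows as (lineno, pattern, value) triples."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rows.append((lineno, fields[0], fields[1]))
    if rows and rows[0][1].lower() == "pattern":
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return rows


def _check_patterns(path, rows) -> int:
    n = len(rows[0][1])
    seen: set[str] = set()
    for lineno, pat, _ in rows:
        if len(pat) != n:
            raise FormatError(
                f"{path}:{lineno}: pattern {pat!r} has length {len(pat)}, expected {n}"
            )
        if any(c not in "01" for c in pat):
            raise FormatError(f"{path}:{lineno}: non-binary pattern {pat!r}")
        if pat in seen:
            raise FormatError(f"{path}:{lineno}: duplicate pattern {pat!r}")
        seen.add(pat)
    return n


def read_counts(path) -> PatternCounts:
    """Read a ``pattern<TAB>count`` table; n is inferred from pattern length."""
    rows = _read_table(path)
    n = _check_patterns(path, rows)
    counts: dict[str, int] = {}
    for lineno, pat, val in rows:
        try:
            y = int(val)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: count {val!r} is not an integer") from None
        if y < 0:
            raise FormatError(f"{path}:{lineno}: negative count {y}")
        counts[pat] = y
    return PatternCounts(n, counts)


def write_counts(counts: PatternCounts, path, comments: list[str] | None = None) -> None:
    """Write a count table in lexicographic pattern order."""
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("pattern\tcount\n")
        for pat in sorted(p for p, y in counts.counts.items() if y > 0):
            fh.write(f"{pat}\t{counts.counts[pat]}\n")


def read_distribution_table(path) -> PatternDistribution:
    """Read a ``pattern<TAB>probability`` table as a PatternDistribution."""
    rows = _read_table(path)
    n = _check_patterns(path, rows)
    probs: dict[str, float] = {}
    for lineno, pat, val in rows:
        try:
            p = float(val)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: probability {val!r} is not a number") from None
        if p < 0:
            raise FormatError(f"{path}:{lineno}: negative probability {p}")
        probs[pat] = p
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-6:
        raise FormatError(f"{path}: probabilities sum to {total:.8g}, not 1")
    return PatternDistribution.from_dict(n, probs)


def write_distribution_table(
    theta: PatternDistribution, path, comments: list[str] | None = None
) -> None:
    """Write a distribution as a ``pattern<TAB>probability`` table."""
    from .patterns import index_bits, pattern_to_string

    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("pattern\tprobability\n")
        bits = index_bits(theta.support, theta.n)
        for row, p in zip(bits, theta.probs):
            if p > 0:
                fh.write(f"{pattern_to_string(row)}\t{p:.6g}\n")


def estimate_frame(counts: PatternCounts, result: EstimationResult) -> pd.DataFrame:
    """Estimate table: pattern, y, y_over_N, theta_hat, spurious per observed pattern."""
    pats = counts.observed_patterns()
    rows = []
    for pat in pats:
        k = encode_pattern(pat)
        y = counts.counts[pat]
        th = result.theta_hat.prob(k)
        rows.append(
            {
                "pattern": pat,
                "y": y,
                "y_over_N": y / counts.n_read,
                "theta_hat": th,
                "spurious": k in result.spurious,
            }
        )
    return pd.DataFrame(rows)


def write_estimate(
    counts: PatternCounts,
    result: EstimationResult,
    path,
    order: str = "lexicographic",
    comments: list[str] | None = None,
) -> pd.DataFrame:
    """Write the estimate table; returns the frame written."""
    df = estimate_frame(counts, result)
    if order == "frequency":
        df = df.sort_values("theta_hat", ascending=False, kind="stable")
    elif order != "lexicographic":
        raise ValueError(f"unknown ordering {order!r}")
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("pattern\ty\ty_over_N\ttheta_hat\tspurious\n")
        for row in df.itertuples(index=False):
            th = "0" if row.theta_hat == 0 else f"{row.theta_hat:.6g}"
            fh.write(
                f"{row.pattern}\t{row.y}\t{row.y_over_N:.6g}\t{th}\t"
                f"{'true' if row.spurious else 'false'}\n"
            )
    return df


def run_estimate(
    counts_path,
    epsilon: float,
    eta,
    mode: str = "fast",
    out_path=None,
    order: str = "lexicographic",
    zero_tol: float | None = None,
    max_iter: int | None = None,
    force: bool = False,
) -> tuple[PatternCounts, EstimationResult]:
    """Full estimation workflow: read counts, fit, write the estimate table."""
    from . import estimator as est

    counts = read_counts(counts_path)
    eta_vec = _parse_eta(eta, counts.n)
    model = ErrorModel(counts.n, epsilon, eta_vec)
    kwargs = {}
    if zero_tol is not None:
        kwargs["zero_candidate_tol"] = zero_tol
    if max_iter is not None:
        kwargs["max_iter"] = max_iter
    if mode == "slow":
        result = estimate_slow(counts, model, force=force, **kwargs)
    elif mode == "fast":
        result = estimate_fast(counts, model, **kwargs)
    else:
        raise ValueError(f"mode must be 'fast' or 'slow', got {mode!r}")
    logger.info(
        "estimate: n=%d N_read=%d mode=%s epsilon=%g eta=%s zero_tol=%g "
        "iterations=%d converged=%s log_likelihood=%.6f boundary_snaps=%d spurious=%d",
        counts.n,
        counts.n_read,
        result.mode,
        model.epsilon,
        np.array2string(model.eta, separator=","),
        zero_tol if zero_tol is not None else est.ZERO_CANDIDATE_TOL,
        result.iterations,
        result.converged,
        result.log_likelihood,
        len(result.boundary_snaps),
        len(result.spurious),
    )
    if out_path is not None:
        comments = [
            f"methpat estimate mode={result.mode} epsilon={model.epsilon} "
            f"eta={','.join(f'{e:g}' for e in model.eta)}",
            f"log_likelihood={result.log_likelihood:.6f} iterations={result.iterations} "
            f"converged={result.converged} spurious={len(result.spurious)}",
        ]
        write_estimate(counts, result, out_path, order=order, comments=comments)
    return counts, result


def run_simulate(
    theta_path,
    n_reads: int,
    epsilon: float,
    eta,
    seed: int,
    out_path,
    latent_path=None,
) -> PatternCounts:
    """Simulation workflow: read true theta, simulate reads, write counts."""
    theta = read_distribution_table(theta_path)
    model = ErrorModel(theta.n, epsilon, _parse_eta(eta, theta.n))
    spec = SimulationSpec(theta=theta, n_reads=n_reads, model=model, seed=seed)
    observed, latent = simulate_counts(spec)
    meta = [
        f"methpat simulate n_reads={n_reads} epsilon={model.epsilon} "
        f"eta={','.join(f'{e:g}' for e in model.eta)} seed={seed}",
        f"theta={theta_path}",
    ]
    write_counts(observed, out_path, comments=meta)
    if latent_path is not None:
        write_counts(latent, latent_path, comments=meta + ["latent true-pattern counts"])
    logger.info(
        "simulate: n=%d n_reads=%d seed=%d observed_patterns=%d",
        theta.n,
        n_reads,
        seed,
        len(observed.observed_patterns()),
    )
    return observed


def run_evaluate(truth_path, estimate_path, out_path) -> pd.DataFrame:
    """Evaluation workflow: threshold table for theta_hat and y/N statistics.

    Requires the estimate table produced by :func:`run_estimate` and the true
    distribution used to simulate the data.
    """
    truth = read_distribution_table(truth_path)
    est = pd.read_csv(estimate_path, sep="\t", comment="#", dtype={"pattern": str})
    required = {"pattern", "y", "y_over_N", "theta_hat"}
    if not required.issubset(est.columns):
        raise FormatError(f"{estimate_path}: missing columns {required - set(est.columns)}")
    bad = [p for p in est["pattern"] if len(p) != truth.n or set(p) - set("01")]
    if bad:
        raise FormatError(f"{estimate_path}: patterns incompatible with truth: {bad}")
    idx = [encode_pattern(p) for p in est["pattern"]]
    stats = {
        "theta_hat": dict(zip(idx, est["theta_hat"].astype(float))),
        "y_over_N": dict(zip(idx, est["y_over_N"].astype(float))),
    }
    blocks = []
    for name, stat in stats.items():
        for o in tpr_fpr_curve(stat, truth):
            blocks.append(
                {
                    "statistic": name,
                    "K": o.threshold,
                    "TP": o.tp,
                    "FP": o.fp,
                    "TN": o.tn,
                    "FN": o.fn,
                    "TPR": o.tpr,
                    "FPR": o.fpr,
                }
            )
    df = pd.DataFrame(blocks)
    out = df.copy()
    for col in ("TPR", "FPR"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(out_path, sep="\t", index=False)
    return df


def _parse_eta(eta, n: int):
    """Accept a scalar, a vector, or a comma-separated string of rates."""
    if isinstance(eta, str):
        parts = [float(x) for x in eta.split(",")]
        eta = parts[0] if len(parts) == 1 else parts
    arr = np.atleast_1d(np.asarray(eta, dtype=float))
    if arr.size not in (1, n):
        raise ValueError(f"eta must be scalar or length {n}, got {arr.size} values")
    return arr[0] if arr.size == 1 else arr
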