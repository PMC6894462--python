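"""Distributed fitting across K data partners and one analysis center.

Each partner holds its individual-level rows and shares only summary
aggregates: per-iteration score vectors S_k and Hessian blocks H_k
during point estimation, and H_k(beta_hat), B_k(beta_hat) once for the
sandwich variance.  Because score, Hessian and meat matrices are all
sums over individuals, summing the site aggregates reproduces the
pooled quantities exactly, so the distributed fit equals the pooled fit
to floating-point reproducibility.

The orchestration in :func:`run_distributed` can optionally route every
message through JSON files in a per-run directory, emulating the manual
file transfer a real multi-site study would use; the in-process path
runs the same partner/center code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import NonConvergenceError, ProtocolError
from .messages import (
    BroadcastMessage,
    Message,
    ScoreMessage,
    VarianceMessage,
    message_digest,
    read_message,
    write_message,
)
from .model import (
    ConvergenceConfig,
    DesignData,
    FitResult,
    _sandwich_from_pieces,
    check_convergence,
    meat_matrix,
    newton_step,
    score_and_hessian,
)

logger = logging.getLogger(__name__)


@dataclass
class SiteData:
    """One data partner's rows.  Never leaves this module in distributed mode."""

    site_id: str
    design: DesignData

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def p(self) -> int:
        return self.design.p


@dataclass(frozen=True)
class TranscriptEntry:
    direction: str  # "partner->center" or "center->partner"
    kind: str  # "score" | "variance" | "broadcast"
    iteration: Optional[int]
    site_id: str
    shape: tuple
    digest: str


@dataclass
class ProtocolTranscript:
    """Ordered audit log of every message exchanged during a run.

    Entries record direction, dimensions and a SHA-256 payload digest;
    the message objects themselves are retained so the run can be
    replayed and verified against the digests.
    """

    entries: list[TranscriptEntry] = field(default_factory=list)
    messages: list[Message] = field(default_factory=list)

    def record(self, msg: Message, direction: str) -> None:
        if isinstance(msg, ScoreMessage):
            kind, it, site, shape = "score", msg.iteration, msg.site_id, (msg.p, msg.p)
        elif isinstance(msg, VarianceMessage):
            kind, it, site, shape = "variance", None, msg.site_id, (msg.p, msg.p)
        elif isinstance(msg, BroadcastMessage):
            kind, it, site, shape = "broadcast", msg.iteration, "analysis_center", (msg.p,)
        else:  # pragma: no cover - guarded by type
            raise TypeError(type(msg))
        self.entries.append(
            TranscriptEntry(
                direction=direction,
                kind=kind,
                iteration=it,
                site_id=site,
                shape=shape,
                digest=message_digest(msg),
            )
        )
        self.messages.append(msg)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.entries if e.kind == kind)

    def n_score_rounds(self) -> int:
        its = {e.iteration for e in self.entries if e.kind == "score"}
        return len(its)

    def verify(self, sites: Sequence[SiteData]) -> bool:
        """Replay every recorded broadcast against the partners.

        Recomputes each partner's score message from the broadcast that
        preceded it and checks the payload digest matches what was
        logged — the audit backing the claim that the transcript fully
        determines the run.
        """
        by_id = {s.site_id: s for s in sites}
        current_beta = None
        for entry, msg in zip(self.entries, self.messages):
            if entry.kind == "broadcast":
                current_beta = msg.beta
            elif entry.kind == "score":
                if current_beta is None:
                    raise ProtocolError("score message precedes any broadcast")
                redo = partner_score_step(
                    by_id[entry.site_id], current_beta, msg.iteration
                )
                if message_digest(redo) != entry.digest:
                    return False
            elif entry.kind == "variance":
                if current_beta is None:
                    raise ProtocolError("variance message precedes any broadcast")
                redo = partner_variance_step(by_id[entry.site_id], current_beta)
                if message_digest(redo) != entry.digest:
                    return False
        return True


# ---------------------------------------------------------------------------
# partner-side operations
# ---------------------------------------------------------------------------


def partner_score_step(site: SiteData, beta: np.ndarray, r: int) -> ScoreMessage:
    """Compute S_k^(r), H_k^(r) over the site's rows for broadcast beta^(r-1)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (site.p,):
        raise ProtocolError(
            f"site {site.site_id!r}: broadcast beta has length {beta.shape[0]} "
            f"but local design has p={site.p}"
        )
    S, H = score_and_hessian(site.design, beta)
    return ScoreMessage(site_id=site.site_id, iteration=int(r), S=S, H=H)


def partner_variance_step(site: SiteData, beta_hat: np.ndarray) -> VarianceMessage:
    """Compute H_k(beta_hat) and B_k(beta_hat); a single non-iterative round."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_hat.shape != (site.p,):
        raise ProtocolError(
            f"site {site.site_id!r}: final beta has length {beta_hat.shape[0]} "
            f"but local design has p={site.p}"
        )
    _, H = score_and_hessian(site.design, beta_hat)
    B = meat_matrix(site.design, beta_hat)
    return VarianceMessage(site_id=site.site_id, H_hat=H, B_hat=B)


# ---------------------------------------------------------------------------
# center-side operations
# ---------------------------------------------------------------------------


def _check_one_per_site(messages, site_ids: Sequence[str]) -> list:
    got = [m.site_id for m in messages]
    dupes = {s for s in got if got.count(s) > 1}
    if dupes:
        raise ProtocolError(f"duplicate messages from sites {sorted(dupes)}")
    missing = [s for s in site_ids if s not in got]
    if missing:
        raise ProtocolError(f"missing messages from sites {missing}")
    extra = [s for s in got if s not in site_ids]
    if extra:
        raise ProtocolError(f"messages from unregistered sites {sorted(set(extra))}")
    by_id = {m.site_id: m for m in messages}
    # fixed registration order: floating-point sums are reproducible run to run
    return [by_id[s] for s in site_ids]


def center_update(
    messages: Sequence[ScoreMessage],
    beta_prev: np.ndarray,
    cfg: ConvergenceConfig,
    site_ids: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, bool, np.ndarray]:
    """Aggregate S = sum_k S_k, H = sum_k H_k; one Newton update + stop check.

    Returns ``(beta_new, converged, deltas)``.
    """
    if not messages:
        raise ProtocolError("center_update received no score messages")
    if site_ids is None:
        site_ids = [m.site_id for m in messages]
    ordered = _check_one_per_site(messages, site_ids)
    its = {m.iteration for m in ordered}
    if len(its) != 1:
        raise ProtocolError(f"score messages disagree on iteration: {sorted(its)}")
    ps = {m.p for m in ordered}
    if len(ps) != 1:
        raise ProtocolError(f"score messages disagree on dimension p: {sorted(ps)}")
    S = np.zeros(ordered[0].p)
    H = np.zeros((ordered[0].p, ordered[0].p))
    for m in ordered:
        S += m.S
        H += m.H
    beta_new = newton_step(beta_prev, S, H)
    converged, deltas = check_convergence(beta_prev, beta_new, cfg)
    return beta_new, converged, deltas


def center_variance(
    messages: Sequence[VarianceMessage],
    site_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Aggregate H = sum_k H_k, B = sum_k B_k; return H^{-1} B H^{-1}."""
    if not messages:
        raise ProtocolError("center_variance received no variance messages")
    if site_ids is None:
        site_ids = [m.site_id for m in messages]
    ordered = _check_one_per_site(messages, site_ids)
    ps = {m.p for m in ordered}
    if len(ps) != 1:
        raise ProtocolError(f"variance messages disagree on dimension p: {sorted(ps)}")
    H = np.zeros((ordered[0].p, ordered[0].p))
    B = np.zeros_like(H)
    for m in ordered:
        H += m.H_hat
        B += m.B_hat
    return _sandwich_from_pieces(H, B)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _via_files(msg: Message, path: Optional[Path]) -> Message:
    """Round-trip a message through its JSON file when file transport is on."""
    if path is None:
        return msg
    write_message(msg, path)
    return read_message(path)


def run_distributed(
    sites: Sequence[SiteData],
    cfg: Optional[ConvergenceConfig] = None,
    beta0: Optional[np.ndarray] = None,
    term_names: Optional[list[str]] = None,
    message_dir=None,
) -> tuple[FitResult, ProtocolTranscript]:
    """Full protocol run: score rounds to convergence, then one variance round.

    ``message_dir``, when given, makes every exchange pass through a JSON
    file in that directory (named ``round###_<site>_<kind>.json``); the
    payloads used downstream are the deserialized ones, so the files are
    a faithful record of the run.
    """
    cfg = cfg or ConvergenceConfig()
    if not sites:
        raise ProtocolError("need at least one data partner")
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ProtocolError(f"site ids are not unique: {ids}")
    ps = {s.p for s in sites}
    if len(ps) != 1:
        raise ProtocolError(
            f"sites disagree on the regressor dimension p: {sorted(ps)}"
        )
    p = ps.pop()
    for s in sites:
        s.design.require_outcome()

    mdir = None
    if message_dir is not None:
        mdir = Path(message_dir)
        mdir.mkdir(parents=True, exist_ok=True)

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    if beta.shape != (p,):
        raise ProtocolError(f"beta0 has length {beta.shape[0]}, expected {p}")

    transcript = ProtocolTranscript()
    trace: list[tuple[np.ndarray, float]] = []
    converged = False
    r = 0
    for r in range(1, cfg.max_iterations + 1):
        bc = BroadcastMessage(iteration=r, beta=beta)
        bc = _via_files(bc, mdir / f"round{r:03d}_broadcast.json" if mdir else None)
        transcript.record(bc, "center->partner")
        score_msgs = []
        for site in sites:
            msg = partner_score_step(site, bc.beta, r)
            msg = _via_files(
                msg, mdir / f"round{r:03d}_{site.site_id}_score.json" if mdir else None
            )
            transcript.record(msg, "partner->center")
            score_msgs.append(msg)
        beta_new, converged, deltas = center_update(score_msgs, beta, cfg, site_ids=ids)
        max_delta = float(np.max(np.abs(deltas)))
        trace.append((beta_new.copy(), max_delta))
        logger.info("iteration %d: max |delta| = %.3e", r, max_delta)
        beta = beta_new
        if converged:
            break
    if not converged:
        raise NonConvergenceError(
            f"distributed fit: no convergence after {cfg.max_iterations} iterations",
            trace=trace,
        )

    final_bc = BroadcastMessage(iteration=r + 1, beta=beta, final=True)
    final_bc = _via_files(
        final_bc, mdir / "final_broadcast.json" if mdir else None
    )
    transcript.record(final_bc, "center->partner")
    var_msgs = []
    for site in sites:
        msg = partner_variance_step(site, final_bc.beta)
        msg = _via_files(
            msg, mdir / f"variance_{site.site_id}.json" if mdir else None
        )
        transcript.record(msg, "partner->center")
        var_msgs.append(msg)
    cov = center_variance(var_msgs, site_ids=ids)

    fit = FitResult(
        beta=beta,
        cov=cov,
        se=np.sqrt(np.diag(cov)),
        n_iterations=r,
        converged=True,
        trace=trace,
        term_names=term_names,
        n_obs=sum(s.n for s in sites),
    )
    return fit, transcript
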