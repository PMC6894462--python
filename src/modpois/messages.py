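"""Cross-site message payloads and their JSON file representation.

In distributed mode the only objects that ever cross a data partner's
boundary are these messages.  Their payloads are p-vectors and p x p
matrices — dimensions set by the number of regressors, never by a site's
sample size — which is the privacy property of the protocol.

Serialization uses Python's shortest round-trip float representation, so
a write/read cycle reproduces every payload bit-for-bit; the file format
is the transcript a study would actually exchange.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .errors import DeserializationError, ProtocolError

PROTOCOL_VERSION = "1.0"

_SYMMETRY_RTOL = 1e-10


def _as_vector(x, what: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ProtocolError(f"{what} must be a vector, got ndim={v.ndim}")
    return v


def _as_square(x, what: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ProtocolError(f"{what} must be a square matrix, got shape {m.shape}")
    return m


def _require_symmetric(m: np.ndarray, what: str) -> None:
    scale = max(float(np.max(np.abs(m))), 1.0)
    if float(np.max(np.abs(m - m.T))) > _SYMMETRY_RTOL * scale:
        raise ProtocolError(f"{what} is not symmetric within tolerance")


@dataclass(frozen=True)
class ScoreMessage:
    """One partner's contribution to a Newton iteration: (S_k, H_k)."""

    site_id: str
    iteration: int
    S: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "S", _as_vector(self.S, "S_k"))
        object.__setattr__(self, "H", _as_square(self.H, "H_k"))
        if self.H.shape[0] != self.S.shape[0]:
            raise ProtocolError(
                f"site {self.site_id!r}: S_k has length {self.S.shape[0]} "
                f"but H_k has shape {self.H.shape}"
            )
        _require_symmetric(self.H, f"site {self.site_id!r} H_k")

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class VarianceMessage:
    """One partner's variance-round contribution: H_k and B_k at beta_hat."""

    site_id: str
    H_hat: np.ndarray
    B_hat: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "H_hat", _as_square(self.H_hat, "H_k(beta_hat)"))
        object.__setattr__(self, "B_hat", _as_square(self.B_hat, "B_k(beta_hat)"))
        if self.H_hat.shape != self.B_hat.shape:
            raise ProtocolError(
                f"site {self.site_id!r}: H_k and B_k shapes differ "
                f"({self.H_hat.shape} vs {self.B_hat.shape})"
            )
        _require_symmetric(self.H_hat, f"site {self.site_id!r} H_k(beta_hat)")
        _require_symmetric(self.B_hat, f"site {self.site_id!r} B_k(beta_hat)")
        eigs = np.linalg.eigvalsh(self.B_hat)
        if eigs.size and eigs[0] < -1e-8 * max(abs(eigs[-1]), 1.0):
            raise ProtocolError(
                f"site {self.site_id!r}: B_k(beta_hat) is not positive semi-definite"
            )

    @property
    def p(self) -> int:
        return self.H_hat.shape[0]


@dataclass(frozen=True)
class BroadcastMessage:
    """The analysis center's coefficient broadcast for iteration ``iteration``."""

    iteration: int
    beta: np.ndarray
    final: bool = False

    def __post_init__(self):
        object.__setattr__(self, "beta", _as_vector(self.beta, "beta broadcast"))

    @property
    def p(self) -> int:
        return self.beta.shape[0]


Message = Union[ScoreMessage, VarianceMessage, BroadcastMessage]


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def message_to_dict(msg: Message) -> dict:
    if isinstance(msg, ScoreMessage):
        return {
            "protocol_version": PROTOCOL_VERSION,
            "kind": "score",
            "site_id": msg.site_id,
            "iteration": int(msg.iteration),
            "payload": {"S": msg.S.tolist(), "H": msg.H.tolist()},
        }
    if isinstance(msg, VarianceMessage):
        return {
            "protocol_version": PROTOCOL_VERSION,
            "kind": "variance",
            "site_id": msg.site_id,
            "iteration": None,
            "payload": {"H": msg.H_hat.tolist(), "B": msg.B_hat.tolist()},
        }
    if isinstance(msg, BroadcastMessage):
        return {
            "protocol_version": PROTOCOL_VERSION,
            "kind": "broadcast",
            "site_id": "analysis_center",
            "iteration": int(msg.iteration),
            "payload": {"beta": msg.beta.tolist(), "final": bool(msg.final)},
        }
    raise TypeError(f"not a protocol message: {type(msg)!r}")


def message_digest(msg: Message) -> str:
    """SHA-256 of the canonical JSON encoding; identifies a payload exactly."""
    canon = json.dumps(message_to_dict(msg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def write_message(msg: Message, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(message_to_dict(msg), fh, indent=1)
    return path


def _finite_array(raw, what: str, site: str) -> np.ndarray:
    try:
        arr = np.asarray(raw, dtype=float)
    except (TypeError, ValueError) as exc:
        raise DeserializationError(f"site {site!r}: {what} is not numeric: {exc}")
    if not np.all(np.isfinite(arr)):
        raise DeserializationError(f"site {site!r}: {what} contains NaN or Inf")
    return arr


def message_from_dict(doc: dict) -> Message:
    if not isinstance(doc, dict):
        raise DeserializationError("message document is not a JSON object")
    missing = {"protocol_version", "kind", "site_id", "iteration", "payload"} - set(doc)
    if missing:
        raise DeserializationError(f"message missing required keys: {sorted(missing)}")
    if doc["protocol_version"] != PROTOCOL_VERSION:
        raise DeserializationError(
            f"unsupported protocol version {doc['protocol_version']!r}"
        )
    kind = doc["kind"]
    site = str(doc["site_id"])
    payload = doc["payload"]
    if not isinstance(payload, dict):
        raise DeserializationError(f"site {site!r}: payload is not an object")
    try:
        if kind == "score":
            S = _finite_array(payload.get("S"), "S", site)
            H = _finite_array(payload.get("H"), "H", site)
            if not isinstance(doc["iteration"], int):
                raise DeserializationError(f"site {site!r}: iteration must be an integer")
            return ScoreMessage(site_id=site, iteration=doc["iteration"], S=S, H=H)
        if kind == "variance":
            H = _finite_array(payload.get("H"), "H", site)
            B = _finite_array(payload.get("B"), "B", site)
            return VarianceMessage(site_id=site, H_hat=H, B_hat=B)
        if kind == "broadcast":
            beta = _finite_array(payload.get("beta"), "beta", site)
            if not isinstance(doc["iteration"], int):
                raise DeserializationError("broadcast iteration must be an integer")
            return BroadcastMessage(
                iteration=doc["iteration"],
                beta=beta,
                final=bool(payload.get("final", False)),
            )
    except ProtocolError as exc:
        if isinstance(exc, DeserializationError):
            raise
        raise DeserializationError(f"site {site!r}: {exc}")
    raise DeserializationError(f"unknown message kind {kind!r}")


def read_message(path) -> Message:
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DeserializationError(f"{path}: invalid JSON: {exc}")
    return message_from_dict(doc)
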