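"""Three-party secure inference: Client, Modeler and Evaluator.

The parties are simulated as functions exchanging files through a session
directory (no network layer), keeping the trust boundary auditable:

* ``client/``     — the secret key; never read by modeler or evaluator code.
* ``public/``     — parameters, the packing plan, and the public,
                    relinearization and Galois keys the client broadcasts.
* ``evaluator/``  — encrypted genotype matrix and encrypted model weights.
* ``predictions/``— encrypted per-phenotype scores plus the op-count audit.

The evaluator role is statically incapable of decryption: it reconstructs a
key bundle whose secret slot is empty and only ever calls homomorphic
operations. The client decrypts the returned scores, unpacks complex rows
back to sample order, trims padding rows and computes 1−NRMSE / AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import serialize as ser
from .ckks import CkksContext, KeyBundle, OpCounter
from .errors import DigestMismatchError, ParameterError
from .lmfi import BINARY, LMFIModel, predict_plain
from .linear_eval import (EncryptedMatrix, EncryptedVector, add_intercept,
                          encrypt_matrix, encrypt_vector,
                          eval_encrypted_matrix, eval_plain_matrix,
                          extract_scores)
from .metrics import average_score, phenotype_score
from .packing import BsgsPlan, encode_matrix, make_plan
from .params import HEParams


@dataclass
class ScoreReport:
    """Per-phenotype accuracies S_k and their mean S̄."""

    kinds: list[str]
    scores: list[float]
    predictions: np.ndarray | None = None

    @property
    def average(self) -> float:
        return average_score(self.scores)

    def as_dict(self) -> dict:
        return {
            "per_phenotype": self.scores,
            "kinds": self.kinds,
            "average": self.average,
        }


def score_predictions(kinds: list[str], Y: np.ndarray,
                      scores: np.ndarray) -> ScoreReport:
    """Apply the S_k case split column-wise and average."""
    Y = np.asarray(Y, dtype=np.float64)
    sc = [phenotype_score(kind, Y[:, k], scores[:, k])
          for k, kind in enumerate(kinds)]
    return ScoreReport(list(kinds), sc, scores)


# ---------------------------------------------------------------------------
# in-memory session (the same steps the file-based roles perform)
# ---------------------------------------------------------------------------
@dataclass
class SessionAudit:
    op_counts: dict[str, int] = field(default_factory=dict)
    per_phenotype_counts: list[dict] = field(default_factory=list)


def run_secure_session(params: HEParams, X_test: np.ndarray, model: LMFIModel,
                       seed: int = 0, encrypt_data_matrix: bool = True,
                       complex_packed: bool = True,
                       ) -> tuple[np.ndarray, SessionAudit]:
    """Full protocol round trip in one process; returns (m×K scores, audit)."""
    ctx = CkksContext(params)
    X_test = np.asarray(X_test, dtype=np.float64)
    plan = make_plan(X_test.shape[0], X_test.shape[1], ctx.N, complex_packed)
    bundle = ctx.keygen(seed, rotation_steps=plan.rotation_steps)
    rng = np.random.default_rng(seed + 1)
    if encrypt_data_matrix:
        data = encrypt_matrix(ctx, X_test, bundle, complex_packed, rng)
    else:
        data = encode_matrix(ctx, X_test, complex_packed)
    audit = SessionAudit()
    cols = []
    total = OpCounter()
    for p in model.phenotypes:
        counter = OpCounter()
        ev = encrypt_vector(ctx, p.weights, plan, bundle, rng)
        if encrypt_data_matrix:
            ct = eval_encrypted_matrix(ctx, data, ev, bundle, counter)
        else:
            ct = eval_plain_matrix(ctx, data, ev, bundle, counter)
        ct = add_intercept(ctx, ct, _encrypt_intercept(ctx, p.intercept, plan,
                                                       bundle, ct, rng))
        cols.append(extract_scores(ctx, ct, plan, bundle))
        audit.per_phenotype_counts.append(counter.as_dict())
        for k, v in counter.as_dict().items():
            total.tick(k, v)
    audit.op_counts = total.as_dict()
    return np.column_stack(cols), audit


def _encrypt_intercept(ctx: CkksContext, w0: float, plan: BsgsPlan,
                       bundle: KeyBundle, ct_like, rng) -> "object":
    """w0 as a self-repeating constant at the result's level and scale; with
    complex packing both the real and imaginary rows receive the shift."""
    value = w0 * (1 + 1j) if plan.complex_packed else w0
    pt = ctx.encode(np.full(ctx.slots, value), scale=ct_like.scale,
                    level=ct_like.level)
    return ctx.encrypt(pt, bundle, rng=rng)


# ---------------------------------------------------------------------------
# file-based roles
# ---------------------------------------------------------------------------
class ProtocolSession:
    """Artifact paths and parameter digest for one session directory."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.client = self.root / "client"
        self.public = self.root / "public"
        self.evaluator = self.root / "evaluator"
        self.predictions = self.root / "predictions"

    def params(self) -> HEParams:
        obj = json.loads((self.public / "params.json").read_text())
        return HEParams(ring_degree=obj["ring_degree"],
                        modulus_chain=tuple(obj["modulus_chain"]),
                        scale=obj["scale"], error_stddev=obj["error_stddev"])

    def plan(self) -> BsgsPlan:
        return ser.plan_from_meta(json.loads((self.public / "plan.json").read_text()))


def client_setup(root: str | Path, params: HEParams, m_rows: int, n_cols: int,
                 seed: int, complex_packed: bool = True) -> ProtocolSession:
    """Generate keys for the declared data shape; broadcast the public parts."""
    sess = ProtocolSession(root)
    for d in (sess.client, sess.public, sess.evaluator, sess.predictions):
        d.mkdir(parents=True, exist_ok=True)
    ctx = CkksContext(params)
    plan = make_plan(m_rows, n_cols, ctx.N, complex_packed)
    bundle = ctx.keygen(seed, rotation_steps=plan.rotation_steps)
    (sess.public / "params.json").write_text(json.dumps({
        "ring_degree": params.ring_degree,
        "modulus_chain": list(params.modulus_chain),
        "scale": params.scale,
        "error_stddev": params.error_stddev,
        "digest": params.digest(),
    }, indent=1))
    (sess.public / "plan.json").write_text(json.dumps(plan.as_dict(), indent=1))
    (sess.public / "public.key").write_bytes(ser.public_key_bytes(bundle))
    (sess.public / "relin.key").write_bytes(ser.relin_key_bytes(bundle))
    (sess.public / "galois.key").write_bytes(ser.galois_keys_bytes(bundle))
    (sess.client / "secret.key").write_bytes(ser.secret_key_bytes(bundle))
    return sess


def _public_bundle(sess: ProtocolSession, ctx: CkksContext) -> KeyBundle:
    """Key bundle from broadcast artifacts only — no secret key inside."""
    digest = ctx.params.digest()
    pa, pb = ser.load_public_key((sess.public / "public.key").read_bytes(), digest)
    relin = ser.load_relin_key((sess.public / "relin.key").read_bytes(), digest)
    galois = ser.load_galois_keys((sess.public / "galois.key").read_bytes(), digest)
    return KeyBundle(ctx.params, None, pa, pb, relin, galois)


def client_encrypt_data(sess: ProtocolSession, X: np.ndarray,
                        seed: int = 1) -> Path:
    """Pad, split, complex-pack, extract pre-rotated diagonals and encrypt."""
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0:
        raise ParameterError("empty genotype matrix")
    ctx = CkksContext(sess.params())
    plan = sess.plan()
    if (X.shape[0], X.shape[1]) != (plan.m_rows, plan.n_cols):
        raise ParameterError("genotype shape differs from the declared plan")
    bundle = _public_bundle(sess, ctx)
    em = encrypt_matrix(ctx, X, bundle, plan.complex_packed,
                        np.random.default_rng(seed))
    flat = [ct for sub in em.cts for ct in sub]
    out = sess.evaluator / "data.emat"
    out.write_bytes(ser.ct_bundle_bytes(flat, ctx.params.digest(),
                                        meta=plan.as_dict()))
    return out


def modeler_encrypt_model(sess: ProtocolSession, model: LMFIModel,
                          seed: int = 2) -> list[Path]:
    """Encrypt each phenotype's weight slices and intercept with the public key."""
    ctx = CkksContext(sess.params())
    plan = sess.plan()
    if model.n_variants != plan.n_cols:
        raise ParameterError("model width differs from the session plan")
    bundle = _public_bundle(sess, ctx)
    rng = np.random.default_rng(seed)
    paths = []
    for k, p in enumerate(model.phenotypes):
        ev = encrypt_vector(ctx, p.weights, plan, bundle, rng)
        w0ct = _encrypt_intercept_artifact(ctx, p.intercept, plan, bundle, rng)
        blob = ser.ct_bundle_bytes(ev.cts + [w0ct], ctx.params.digest(),
                                   meta={**plan.as_dict(), "kind": p.kind,
                                         "name": p.name})
        path = sess.evaluator / f"model_{k}.evec"
        path.write_bytes(blob)
        paths.append(path)
    return paths


def _encrypt_intercept_artifact(ctx, w0, plan, bundle, rng):
    value = w0 * (1 + 1j) if plan.complex_packed else w0
    pt = ctx.encode(np.full(ctx.slots, value), scale=ctx.params.scale,
                    level=ctx.top_level - 1)
    return ctx.encrypt(pt, bundle, rng=rng)


def evaluator_predict(sess: ProtocolSession) -> Path:
    """Homomorphic inference with public key material only."""
    ctx = CkksContext(sess.params())
    digest = ctx.params.digest()
    bundle = _public_bundle(sess, ctx)
    flat, meta = ser.ct_bundle_from_bytes((sess.evaluator / "data.emat").read_bytes(),
                                          digest)
    plan = ser.plan_from_meta(meta)
    per_sub = [flat[i * plan.l : (i + 1) * plan.l] for i in range(plan.s)]
    em = EncryptedMatrix(plan, per_sub, flat[0].scale)
    outs, audit = [], []
    model_paths = sorted(sess.evaluator.glob("model_*.evec"),
                         key=lambda p: int(p.stem.split("_")[1]))
    for path in model_paths:
        cts, mmeta = ser.ct_bundle_from_bytes(path.read_bytes(), digest)
        if ser.plan_from_meta(mmeta) != plan:
            raise DigestMismatchError("model artifact packed under another plan")
        ev = EncryptedVector(plan, cts[:-1], cts[0].scale)
        counter = OpCounter()
        ct = eval_encrypted_matrix(ctx, em, ev, bundle, counter)
        ct = add_intercept(ctx, ct, cts[-1])
        outs.append(ct)
        audit.append({"phenotype": mmeta.get("name", path.stem),
                      "kind": mmeta.get("kind"), **counter.as_dict()})
    out = sess.predictions / "scores.ctbl"
    out.write_bytes(ser.ct_bundle_bytes(outs, digest, meta=plan.as_dict()))
    (sess.predictions / "audit.json").write_text(json.dumps(audit, indent=1))
    return out


def client_decrypt_scores(sess: ProtocolSession) -> np.ndarray:
    """Decrypt predictions, invert the packing and drop padded rows."""
    ctx = CkksContext(sess.params())
    digest = ctx.params.digest()
    cts, meta = ser.ct_bundle_from_bytes(
        (sess.predictions / "scores.ctbl").read_bytes(), digest)
    plan = ser.plan_from_meta(meta)
    secret = ser.load_secret_key((sess.client / "secret.key").read_bytes(), digest)
    bundle = KeyBundle(ctx.params, secret, None, None, None)
    cols = [extract_scores(ctx, ct, plan, bundle) for ct in cts]
    return np.column_stack(cols)


def run_file_session(root: str | Path, params: HEParams, X: np.ndarray,
                     model: LMFIModel, seed: int = 0,
                     complex_packed: bool = True) -> np.ndarray:
    """All five protocol steps through the session directory."""
    sess = client_setup(root, params, X.shape[0], X.shape[1], seed,
                        complex_packed)
    client_encrypt_data(sess, X, seed + 1)
    modeler_encrypt_model(sess, model, seed + 2)
    evaluator_predict(sess)
    return client_decrypt_scores(sess)
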