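"""The dual-encoder regression model.

Two separate directed message-passing encoders — one for the condensed graph
of reaction, one for the solvent molecular graph — produce embeddings that
are concatenated (together with optional molecular extras such as the
reactant/product solvation energies) and passed through a feed-forward head
predicting the two targets, ddG‡_solv and ddH‡_solv at 298 K in kcal/mol.
Targets are standardized with training-split statistics stored in the
bundle, so predictions are de-normalized on the way out.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import FeatureError, SchemaError, ShapeError, UsageError
from .featurize import (
    CGRGraph,
    FeatureSchema,
    MolGraph,
    batch_graphs,
    build_cgr,
    build_mol_graph,
)
from .nn import (
    EncoderParams,
    HeadParams,
    encoder_backward,
    encoder_forward,
    head_backward,
    head_forward,
    init_encoder,
    init_head,
)
from .pairtable import PairRecord

__all__ = [
    "ModelBundle",
    "new_bundle",
    "featurize_records",
    "predict_records",
    "predict_pair",
    "ensemble_predict",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "kinsolv-checkpoint-1"


@dataclass
class ModelBundle:
    """A complete parameter set: two distinct encoders, the head, and the
    target normalization statistics."""

    cgr_encoder: EncoderParams
    solvent_encoder: EncoderParams
    head: HeadParams
    schema: FeatureSchema
    target_mean: np.ndarray
    target_std: np.ndarray
    extras_dim: int = 0
    rxn_readout: str = "mean"
    solvent_readout: str = "mean"
    seed: int = 0
    fingerprint: str = field(default="", repr=False)

    def __post_init__(self):
        if not self.fingerprint:
            self.fingerprint = self.config_fingerprint()

    def architecture(self) -> Dict:
        return {
            "schema_version": self.schema.version,
            "include_chirality": self.schema.include_chirality,
            "extra_atom_features": self.schema.extra_atom_features,
            "hidden": self.cgr_encoder.hidden,
            "depth": self.cgr_encoder.depth,
            "solvent_hidden": self.solvent_encoder.hidden,
            "solvent_depth": self.solvent_encoder.depth,
            "ffn": [w.shape[1] for w in self.head.weights[:-1]],
            "extras_dim": self.extras_dim,
            "rxn_readout": self.rxn_readout,
            "solvent_readout": self.solvent_readout,
        }

    def config_fingerprint(self) -> str:
        blob = json.dumps(self.architecture(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def param_arrays(self) -> Dict[str, np.ndarray]:
        out = {}
        out.update(self.cgr_encoder.arrays("cgr"))
        out.update(self.solvent_encoder.arrays("solv"))
        out.update(self.head.arrays("head"))
        return out

    def normalize(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean) / self.target_std

    def denormalize(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_std + self.target_mean

    def copy(self) -> "ModelBundle":
        return copy.deepcopy(self)


def new_bundle(
    schema: Optional[FeatureSchema] = None,
    hidden: int = 300,
    depth: int = 3,
    ffn_hidden: Tuple[int, ...] = (300, 300),
    extras_dim: int = 0,
    rxn_readout: str = "mean",
    solvent_readout: str = "mean",
    seed: int = 0,
) -> ModelBundle:
    """Fresh bundle with two independently initialized encoders (the two
    encoders never share weights)."""
    schema = schema or FeatureSchema()
    cgr = init_encoder(
        schema.cgr_atom_width, schema.cgr_bond_width, hidden, depth, seed=seed * 3 + 1
    )
    solv = init_encoder(
        schema.atom_width, schema.bond_width, hidden, depth, seed=seed * 3 + 2
    )
    head = init_head(2 * hidden + extras_dim, ffn_hidden, 2, seed=seed * 3 + 3)
    return ModelBundle(
        cgr_encoder=cgr,
        solvent_encoder=solv,
        head=head,
        schema=schema,
        target_mean=np.zeros(2),
        target_std=np.ones(2),
        extras_dim=extras_dim,
        rxn_readout=rxn_readout,
        solvent_readout=solvent_readout,
        seed=seed,
    )


@dataclass
class FeaturizedRecord:
    cgr: CGRGraph
    solvent: MolGraph
    extras: Optional[np.ndarray]


def featurize_records(
    records: Sequence[PairRecord],
    schema: FeatureSchema,
    cache: Optional[Dict] = None,
) -> List[FeaturizedRecord]:
    """Featurize records, caching per unique reaction and solvent string."""
    cache = cache if cache is not None else {}
    out = []
    for rec in records:
        rkey = ("cgr", rec.reaction.smiles)
        if rkey not in cache:
            cache[rkey] = build_cgr(rec.reaction, schema)
        skey = ("solv", rec.solvent)
        if skey not in cache:
            cache[skey] = build_mol_graph(rec.solvent, schema)
        out.append(FeaturizedRecord(cache[rkey], cache[skey], rec.extras))
    return out


def _extras_matrix(feats: Sequence[FeaturizedRecord], extras_dim: int) -> np.ndarray:
    if extras_dim == 0:
        return np.zeros((len(feats), 0))
    rows = []
    for f in feats:
        if f.extras is None or f.extras.shape[0] != extras_dim:
            have = 0 if f.extras is None else f.extras.shape[0]
            raise FeatureError(
                f"record extras width {have} does not match model extras_dim "
                f"{extras_dim}"
            )
        rows.append(f.extras)
    return np.stack(rows)


def forward_records(
    feats: Sequence[FeaturizedRecord],
    bundle: ModelBundle,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    want_cache: bool = False,
):
    """Normalized-scale predictions (n, 2) for a batch of records."""
    rxn_batch = batch_graphs([f.cgr for f in feats])
    solv_batch = batch_graphs([f.solvent for f in feats])
    extras = _extras_matrix(feats, bundle.extras_dim)
    rxn_emb, rxn_cache = encoder_forward(
        rxn_batch, bundle.cgr_encoder, bundle.rxn_readout, dropout, rng, True
    )
    solv_emb, solv_cache = encoder_forward(
        solv_batch, bundle.solvent_encoder, bundle.solvent_readout, dropout, rng, True
    )
    x = np.concatenate([rxn_emb, solv_emb, extras], axis=1)
    preds, head_cache = head_forward(x, bundle.head, dropout, rng, True)
    if not want_cache:
        return preds
    cache = {
        "rxn": rxn_cache,
        "solv": solv_cache,
        "head": head_cache,
        "split": (rxn_emb.shape[1], solv_emb.shape[1]),
    }
    return preds, cache


def backward_records(
    d_preds: np.ndarray, cache: Dict, bundle: ModelBundle
) -> Dict[str, np.ndarray]:
    head_grads, d_x = head_backward(d_preds, cache["head"], bundle.head)
    h_rxn, h_solv = cache["split"]
    grads = {f"head.{k}": v for k, v in head_grads.items()}
    rxn_grads = encoder_backward(d_x[:, :h_rxn], cache["rxn"], bundle.cgr_encoder)
    solv_grads = encoder_backward(
        d_x[:, h_rxn:h_rxn + h_solv], cache["solv"], bundle.solvent_encoder
    )
    grads.update({f"cgr.{k}": v for k, v in rxn_grads.items()})
    grads.update({f"solv.{k}": v for k, v in solv_grads.items()})
    return grads


def predict_records(
    records: Sequence[PairRecord],
    bundle: ModelBundle,
    cache: Optional[Dict] = None,
) -> np.ndarray:
    """De-normalized predictions (n, 2) in kcal/mol."""
    feats = featurize_records(records, bundle.schema, cache)
    preds = forward_records(feats, bundle)
    return bundle.denormalize(preds)


def predict_pair(record: PairRecord, bundle: ModelBundle) -> Tuple[float, float]:
    """(ddG_pred, ddH_pred) at 298 K in kcal/mol for one reaction-solvent
    pair."""
    out = predict_records([record], bundle)[0]
    return float(out[0]), float(out[1])


def ensemble_predict(
    bundles: Sequence[ModelBundle],
    records: Sequence[PairRecord],
    cache: Optional[Dict] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ensemble mean and spread over models.

    Returns ``(mean, spread)``, each (n, 2); the spread is the sample
    standard deviation between members (zero for a single model).
    """
    if len(bundles) == 0:
        raise UsageError("ensemble_predict needs at least one model bundle")
    stack = np.stack([predict_records(records, b, cache) for b in bundles])
    mean = stack.mean(axis=0)
    spread = (
        stack.std(axis=0, ddof=1) if len(bundles) > 1 else np.zeros_like(mean)
    )
    return mean, spread


def save_checkpoint(bundle: ModelBundle, path) -> None:
    """Write a single-archive checkpoint: JSON manifest plus all weight
    arrays as little-endian 32-bit reals (target statistics kept at full
    precision)."""
    manifest = {
        "format": CHECKPOINT_FORMAT,
        "architecture": bundle.architecture(),
        "fingerprint": bundle.fingerprint,
        "seed": bundle.seed,
        "target_mean": bundle.target_mean.tolist(),
        "target_std": bundle.target_std.tolist(),
    }
    arrays = {
        k.replace(".", "__"): v.astype("<f4")
        for k, v in bundle.param_arrays().items()
    }
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelBundle:
    """Load and verify a checkpoint archive."""
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        if manifest.get("format") != CHECKPOINT_FORMAT:
            raise SchemaError(
                f"unsupported checkpoint format {manifest.get('format')!r}"
            )
        arch = manifest["architecture"]
        schema = FeatureSchema(
            include_chirality=arch["include_chirality"],
            extra_atom_features=arch["extra_atom_features"],
            version=arch["schema_version"],
        )
        if schema.version != FeatureSchema().version:
            raise SchemaError(
                f"checkpoint feature schema {schema.version!r} is not "
                f"compatible with this build"
            )
        bundle = new_bundle(
            schema=schema,
            hidden=arch["hidden"],
            depth=arch["depth"],
            ffn_hidden=tuple(arch["ffn"]),
            extras_dim=arch["extras_dim"],
            rxn_readout=arch["rxn_readout"],
            solvent_readout=arch["solvent_readout"],
            seed=manifest["seed"],
        )
        bundle.target_mean = np.array(manifest["target_mean"])
        bundle.target_std = np.array(manifest["target_std"])
        params = bundle.param_arrays()
        for name, arr in params.items():
            key = name.replace(".", "__")
            if key not in data:
                raise SchemaError(f"checkpoint is missing weight block {name!r}")
            stored = data[key].astype(np.float64)
            if stored.shape != arr.shape:
                raise ShapeError(
                    f"checkpoint block {name!r} has shape {stored.shape}, "
                    f"expected {arr.shape}"
                )
            arr[...] = stored
        if bundle.config_fingerprint() != manifest["fingerprint"]:
            raise SchemaError("checkpoint fingerprint does not match its config")
    return bundle
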