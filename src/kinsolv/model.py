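"""Model/Results facade over the training machinery.

``KineticSolventEffectModel`` is constructed from a table of reaction-solvent
pairs; ``fit()`` runs the fold/ensemble protocol and returns a
``KineticSolventEffectResults`` carrying the trained bundles, their training
histories, fold-wise test metrics, and prediction/summary/plotting methods.

Typical use::

    records = fixture_dataset(50, 20)
    model = KineticSolventEffectModel(records)
    res = model.fit(mode="reaction", k_folds=1, ensemble_size=1, max_epochs=30)
    print(res.summary())
    preds = res.predict(new_records)            # ddG/ddH at 298 K, kcal/mol
    res2 = model_ft.fit(init=res)               # transfer learning
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .curation import SplitAssignment, make_folds
from .errors import UsageError
from .network import (
    ModelBundle,
    ensemble_predict,
    load_checkpoint,
    save_checkpoint,
)
from .pairtable import PairRecord, TableSchema, read_pair_table, records_from_dataframe
from .thermo import ThermoContext, extrapolate_ddG, log10_rate_ratio_liq_gas
from .train import (
    TrainConfig,
    TrainHistory,
    build_ensemble,
    evaluate,
    evaluate_folds,
)

__all__ = [
    "KineticSolventEffectModel",
    "KineticSolventEffectResults",
    "predict_end_to_end",
]


class KineticSolventEffectModel:
    """Dual-encoder regression of ddG‡_solv / ddH‡_solv for reaction-solvent
    pairs, with leakage-safe grouped splits and ensembling."""

    def __init__(
        self,
        records: Sequence[PairRecord],
        config: Optional[TrainConfig] = None,
    ):
        if len(records) == 0:
            raise UsageError("no records given")
        self.records = list(records)
        self.config = config or TrainConfig()
        self._feature_cache: Dict = {}

    @classmethod
    def from_dataframe(cls, df, schema: Optional[TableSchema] = None, **kwargs):
        return cls(records_from_dataframe(df, schema), **kwargs)

    @classmethod
    def from_csv(cls, path, schema: Optional[TableSchema] = None, **kwargs):
        return cls(read_pair_table(path, schema), **kwargs)

    def fit(
        self,
        mode: str = "reaction",
        k_folds: int = 1,
        test_frac: float = 0.05,
        val_frac: float = 0.2,
        folds: Optional[Sequence[SplitAssignment]] = None,
        init: Optional[Union["KineticSolventEffectResults", Sequence[ModelBundle]]] = None,
        **overrides,
    ) -> "KineticSolventEffectResults":
        """Train ``k_folds x ensemble_size`` models and evaluate each fold's
        ensemble on its own held-out test records.

        ``init`` (a previous Results or a bundle sequence) switches to
        transfer learning: every member starts from its pre-trained
        counterpart.  Keyword overrides patch the TrainConfig, e.g.
        ``max_epochs=10`` for fine-tuning.
        """
        config = replace(self.config, **overrides) if overrides else self.config
        if folds is None:
            folds = make_folds(
                self.records, k=k_folds, mode=mode,
                test_frac=test_frac, val_frac=val_frac, seed=config.seed,
            )
        init_bundles = None
        if init is not None:
            init_bundles = list(init.bundles if hasattr(init, "bundles") else init)
            needed = len(folds) * config.ensemble_size
            if len(init_bundles) == 1:
                init_bundles = init_bundles * needed
            if len(init_bundles) != needed:
                raise UsageError(
                    f"init provides {len(init_bundles)} bundles, need {needed}"
                )
        histories: List[TrainHistory] = []
        bundles = build_ensemble(
            self.records, folds, config,
            init=init_bundles, cache=self._feature_cache, histories=histories,
        )
        return KineticSolventEffectResults(
            model=self,
            config=config,
            folds=list(folds),
            bundles=bundles,
            histories=histories,
        )


@dataclass
class KineticSolventEffectResults:
    """Fitted ensembles plus their evaluation and prediction interface."""

    model: KineticSolventEffectModel
    config: TrainConfig
    folds: List[SplitAssignment]
    bundles: List[ModelBundle]
    histories: List[TrainHistory]
    _metrics: Optional[Dict[str, float]] = field(default=None, repr=False)

    def fold_bundles(self, f: int) -> List[ModelBundle]:
        k = self.config.ensemble_size
        return self.bundles[f * k:(f + 1) * k]

    def fold_test_records(self, f: int) -> List[PairRecord]:
        idx = self.folds[f].indices("test")
        return [self.model.records[i] for i in idx]

    @property
    def metrics(self) -> Dict[str, float]:
        """Fold-wise mean +/- sd of the ensemble-mean test MAE/RMSE."""
        if self._metrics is None:
            per_fold = []
            for f in range(len(self.folds)):
                test = self.fold_test_records(f)
                if test:
                    per_fold.append((self.fold_bundles(f), test))
            if not per_fold:
                raise UsageError(
                    "no fold has test records; evaluate on external data instead"
                )
            self._metrics = evaluate_folds(per_fold, cache=self.model._feature_cache)
        return self._metrics

    def evaluate(self, records: Sequence[PairRecord], unit: str = "kcal/mol"):
        """Metrics of the full ensemble on an external record set."""
        return evaluate(self.bundles, records, unit, cache=self.model._feature_cache)

    def predict(self, records: Sequence[PairRecord]):
        """DataFrame of ensemble predictions: ddG_pred/ddH_pred (kcal/mol at
        298 K) and the ensemble spread per target."""
        import pandas as pd

        mean, spread = ensemble_predict(
            self.bundles, records, cache=self.model._feature_cache
        )
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in records],
                "ddG_pred": mean[:, 0],
                "ddH_pred": mean[:, 1],
                "ddG_sd": spread[:, 0],
                "ddH_sd": spread[:, 1],
            }
        )

    def predict_rate_ratio(self, records: Sequence[PairRecord], T: float = 298.0):
        """Predictions converted to kinetic solvent effects: ddG‡_solv(T) by
        linear extrapolation and log10(k_liq/k_gas) at T."""
        df = self.predict(records)
        ctx = ThermoContext().at(T)
        df["ddG_T"] = [
            extrapolate_ddG(g, h, T) for g, h in zip(df["ddG_pred"], df["ddH_pred"])
        ]
        df["log10_k_liq_over_k_gas"] = [
            log10_rate_ratio_liq_gas(g, ctx) for g in df["ddG_T"]
        ]
        return df

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression results
        summary."""
        recs = self.model.records
        n_rxn = len({r.reaction_key for r in recs})
        n_solv = len({r.solvent_key for r in recs})
        m = self.metrics
        lines = [
            "Kinetic solvent effect model (CGR dual-encoder ensemble)",
            "=" * 60,
            f"records: {len(recs):>8d}    reactions: {n_rxn}    solvents: {n_solv}",
            f"folds:   {len(self.folds):>8d}    ensemble:  {self.config.ensemble_size}"
            f"    mode: {self.folds[0].mode}",
            f"hidden:  {self.config.hidden:>8d}    depth:     {self.config.depth}"
            f"    max epochs: {self.config.max_epochs}",
            "-" * 60,
            "test metrics (ensemble mean; fold mean +/- sd, kcal/mol)",
            f"  ddG‡_solv  MAE  {m['ddG_mae']:7.3f} +/- {m['ddG_mae_sd']:.3f}"
            f"    RMSE {m['ddG_rmse']:7.3f} +/- {m['ddG_rmse_sd']:.3f}",
            f"  ddH‡_solv  MAE  {m['ddH_mae']:7.3f} +/- {m['ddH_mae_sd']:.3f}"
            f"    RMSE {m['ddH_rmse']:7.3f} +/- {m['ddH_rmse_sd']:.3f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def save(self, directory) -> List[str]:
        """Write one checkpoint archive per bundle; returns the paths."""
        import os

        os.makedirs(directory, exist_ok=True)
        paths = []
        for i, bundle in enumerate(self.bundles):
            path = os.path.join(directory, f"model_{i:03d}.npz")
            save_checkpoint(bundle, path)
            paths.append(path)
        return paths

    @staticmethod
    def load_bundles(paths) -> List[ModelBundle]:
        return [load_checkpoint(p) for p in paths]

    def plot_history(self, ax=None):
        """Training/validation loss curves of every member (diagnostics)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, hist in enumerate(self.histories):
            ax.plot(hist.train_loss, alpha=0.5, label=f"train {i}" if i == 0 else None)
            ax.plot(hist.val_loss, alpha=0.5, ls="--",
                    label=f"val {i}" if i == 0 else None)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss (normalized MSE)")
        ax.legend()
        return ax


def predict_end_to_end(
    reaction_smiles: str,
    solvent_smiles: str,
    bundles: Sequence[ModelBundle],
    T: Optional[float] = None,
) -> Dict[str, float]:
    """One-call prediction from raw SMILES strings.

    Returns ddG‡_solv/ddH‡_solv at 298 K (kcal/mol) with the ensemble
    spread; with ``T`` given, also the extrapolated ddG‡_solv(T) and
    log10(k_liq/k_gas) at T (a warning is raised outside 250-400 K, where
    the linear extrapolation degrades).
    """
    from .reactions import parse_mapped_reaction

    record = PairRecord(
        reaction=parse_mapped_reaction(reaction_smiles),
        solvent=solvent_smiles,
        ddG298=0.0,
        ddH298=0.0,
        record_id="query",
    )
    mean, spread = ensemble_predict(bundles, [record])
    out = {
        "ddG298": float(mean[0, 0]),
        "ddH298": float(mean[0, 1]),
        "ddG298_sd": float(spread[0, 0]),
        "ddH298_sd": float(spread[0, 1]),
    }
    if T is not None:
        ddG_T = extrapolate_ddG(out["ddG298"], out["ddH298"], T)
        out["T"] = float(T)
        out["ddG_T"] = ddG_T
        out["log10_k_liq_over_k_gas"] = log10_rate_ratio_liq_gas(
            ddG_T, ThermoContext().at(T)
        )
    return out
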