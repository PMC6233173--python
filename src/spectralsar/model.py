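"""Sequence–activity model and results objects.

`SequenceActivityModel` holds a variant dataset (activities plus
equal-length sequences, usually a wild type and its point mutants), an
encoding index and the encoding configuration.  `fit()` encodes the
sequences into protein spectra (or raw signals in no-FFT mode), selects
the PLS component count by leave-one-out cross-validation unless one is
given, fits on the full set, and returns a
:class:`SequenceActivityResults` carrying the fitted regression, the
cross-validation report and diagnostic metrics.

From the results object hang prediction on new sequences or genotypes,
exhaustive recombinant prediction/ranking over the 2^n combinations of
the learned single mutations, epistasis analysis against the additive
baseline, a text `summary()`, and JSON (de)serialization.
"""
from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .aaindex import EncodingIndex
from .encoding import Energy, Mode, encode_dataset
from .landscape import (
    ACTIVITY_UNITS,
    Genotype,
    PointMutation,
    ThermoParams,
    additive_prediction,
    apply_genotype,
    build_epistasis_records,
    ddg_to_evalue,
    enumerate_genotypes,
    epistasis_table,
    evalue_to_ddg,
    format_genotype,
    parse_genotype,
    rank_variants,
)
from .pls import (
    CVReport,
    PLSModel,
    PredictionSet,
    cross_validate,
    fit_pls,
    predict,
    r_squared,
    rmse,
    select_components,
)


class SequenceActivityModel:
    """Spectral sequence–activity model for a set of protein variants.

    Parameters
    ----------
    activities : array-like
        Measured activity per variant, on the ΔΔG‡ (kcal/mol) or
        E-value scale according to ``activity_unit``.
    sequences : sequence of str
        Equal-length variant sequences (substitution-only variants).
    ids : sequence of str, optional
        Unique variant labels; defaults to ``v0..v{n-1}``.
    index : EncodingIndex
        Per-residue encoding used to build the numeric signals.
    mode : {"fft", "no_fft"}
        Feature construction: protein-spectrum energies, or raw
        per-position values (the linear ablation).
    pad_to, energy, scale
        Spectrum padding, energy definition (|S|² or |S|), and optional
        unit-variance feature scaling.
    wt_sequence, genotypes
        Optional wild-type sequence and per-variant mutation tuples;
        required for recombinant enumeration and epistasis analysis
        (provided automatically by :meth:`from_variant_table`).
    """

    def __init__(
        self,
        activities: Sequence[float],
        sequences: Sequence[str],
        ids: Sequence[str] | None = None,
        *,
        index: EncodingIndex,
        mode: Mode = "fft",
        pad_to: int | None = None,
        energy: Energy = "squared",
        scale: bool = False,
        activity_unit: str = "ddg_kcal_per_mol",
        wt_sequence: str | None = None,
        genotypes: Sequence[Genotype] | None = None,
        thermo: ThermoParams = ThermoParams(),
    ) -> None:
        if activity_unit not in ACTIVITY_UNITS:
            raise ValueError(f"unknown activity unit {activity_unit!r}")
        self.endog = np.asarray(activities, dtype=float)
        self.sequences = [str(s) for s in sequences]
        if len(self.endog) != len(self.sequences):
            raise ValueError("activities and sequences must have equal length")
        self.ids = (
            [str(i) for i in ids]
            if ids is not None
            else [f"v{i}" for i in range(len(self.sequences))]
        )
        self.index = index
        self.mode: Mode = mode
        self.pad_to = pad_to
        self.energy: Energy = energy
        self.scale = scale
        self.activity_unit = activity_unit
        self.wt_sequence = wt_sequence
        self.genotypes = list(genotypes) if genotypes is not None else None
        self.thermo = thermo
        self.exog = encode_dataset(
            self.sequences, self.ids, index, mode=mode, pad_to=pad_to, energy=energy
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_variant_table(
        cls,
        wt_sequence: str,
        variants: pd.DataFrame,
        index: EncodingIndex,
        **kwargs,
    ) -> "SequenceActivityModel":
        """Build a model from a variant table (id, mutations, activity).

        Mutation strings are validated against the wild type and applied
        to produce the variant sequences.  The table's ``activity_unit``
        column (single unit) sets the model's unit unless overridden.
        """
        genotypes = [parse_genotype(m, wt_sequence) for m in variants["mutations"]]
        sequences = [apply_genotype(wt_sequence, g) for g in genotypes]
        if "activity_unit" in variants.columns and "activity_unit" not in kwargs:
            units = set(variants["activity_unit"].unique())
            if len(units) != 1:
                raise ValueError("variant table mixes activity units")
            kwargs["activity_unit"] = units.pop()
        return cls(
            variants["activity"].to_numpy(dtype=float),
            sequences,
            ids=variants["id"].tolist(),
            index=index,
            wt_sequence=wt_sequence,
            genotypes=genotypes,
            **kwargs,
        )

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        n_components: int | None = None,
        max_components: int = 10,
        cv_scheme: str = "loocv",
        k: int | None = None,
        seed: int = 0,
    ) -> "SequenceActivityResults":
        """Select components (LOOCV RMSE, unless given), cross-validate, fit on all.

        Returns a :class:`SequenceActivityResults`.
        """
        if n_components is None:
            n_components = select_components(
                self.exog, self.endog, max_components=max_components, scale=self.scale
            )
        # LOOCV training folds have one sample fewer than the full set, so
        # a full-component request is cross-validated at the fold-feasible cap.
        n = len(self.endog)
        fold = n - 1 if cv_scheme == "loocv" else n - (n // (k or 2) + 1)
        cv_components = min(n_components, fold - 1, self.exog.n_features)
        cv = cross_validate(
            self.exog,
            self.endog,
            n_components=cv_components,
            scheme=cv_scheme,  # type: ignore[arg-type]
            k=k,
            seed=seed,
            scale=self.scale,
        )
        pls = fit_pls(self.exog, self.endog, n_components=n_components, scale=self.scale)
        full = PredictionSet(
            y=self.endog, y_hat=pls.fitted_values, ids=tuple(self.ids)
        )
        cv = replace(
            cv, full_set_r2=r_squared(full), full_set_rmse=rmse(full)
        )
        return SequenceActivityResults(self, pls, cv)

    # -- helpers ----------------------------------------------------------

    def training_singles(self) -> tuple[float, dict[PointMutation, float]]:
        """Wild-type activity and single-mutant activity map from the data."""
        if self.genotypes is None:
            raise ValueError("model was not built from genotypes (use from_variant_table)")
        wt_value = None
        singles: dict[PointMutation, float] = {}
        for g, a in zip(self.genotypes, self.endog):
            if len(g) == 0:
                wt_value = float(a)
            elif len(g) == 1:
                singles[g[0]] = float(a)
        if wt_value is None:
            raise ValueError("training data has no wild-type variant")
        return wt_value, singles


class SequenceActivityResults:
    """Fitted sequence–activity model: estimates, diagnostics, predictions."""

    def __init__(
        self, model: SequenceActivityModel, pls: PLSModel, cv: CVReport
    ) -> None:
        self.model = model
        self.pls = pls
        self.cv = cv
        self.n_components = pls.n_components
        self.loocv_r2 = cv.r2
        self.loocv_rmse = cv.rmse
        self.full_set_r2 = cv.full_set_r2
        self.full_set_rmse = cv.full_set_rmse

    # -- prediction -------------------------------------------------------

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.pls.fitted_values

    def predict_sequences(self, sequences: Sequence[str]) -> np.ndarray:
        """Predict activity for new sequences (same length as training)."""
        fm = encode_dataset(
            sequences,
            [f"q{i}" for i in range(len(sequences))],
            self.model.index,
            mode=self.model.mode,
            pad_to=self.model.pad_to,
            energy=self.model.energy,
        )
        return predict(self.pls, fm)

    def predict_genotypes(self, genotypes: Sequence[Genotype]) -> np.ndarray:
        """Predict activity for genotypes applied to the wild type."""
        wt = self.model.wt_sequence
        if wt is None:
            raise ValueError("no wild-type sequence attached to the model")
        return self.predict_sequences([apply_genotype(wt, g) for g in genotypes])

    def predict_recombinants(
        self, singles: Sequence[PointMutation] | None = None
    ) -> pd.DataFrame:
        """Predict and rank all 2^n recombinants of the single mutations.

        ``singles`` defaults to the single mutations present in the
        training data.  The returned frame is ranked best-first in the
        training unit and carries the converted unit alongside
        (``predicted_ddg`` / ``predicted_e_value``), plus an
        ``in_training_set`` flag.
        """
        if singles is None:
            _, single_map = self.model.training_singles()
            singles = sorted(single_map)
        genotypes = enumerate_genotypes(list(singles))
        preds = self.predict_genotypes(genotypes)
        ids = [format_genotype(g) for g in genotypes]
        frame = pd.DataFrame(
            {"id": ids, "n_mutations": [len(g) for g in genotypes], "predicted": preds}
        )
        thermo = self.model.thermo
        if self.model.activity_unit == "ddg_kcal_per_mol":
            frame["predicted_ddg"] = frame["predicted"]
            frame["predicted_e_value"] = [ddg_to_evalue(v, thermo) for v in preds]
        else:
            frame["predicted_e_value"] = frame["predicted"]
            frame["predicted_ddg"] = [evalue_to_ddg(v, thermo) for v in preds]
        training_ids = [
            format_genotype(g) for g in (self.model.genotypes or [])
        ]
        return rank_variants(
            frame,
            unit=self.model.activity_unit,
            value_column="predicted",
            training_ids=training_ids,
        )

    # -- epistasis --------------------------------------------------------

    def epistasis(
        self,
        genotypes: Sequence[Genotype] | None = None,
        observed: Sequence[float] | None = None,
        ids: Sequence[str] | None = None,
        tol: float = 0.0,
        model_name: str = "model",
        extra_models: Mapping[str, "SequenceActivityResults"] | None = None,
    ) -> pd.DataFrame:
        """Additive baseline, epistasis class and model-vs-additive flags.

        By default analyses the training set's multi-point mutants
        (observed activities from the data); alternatively pass
        explicit genotypes and observed values.  Each model column gets
        an ``I``/``A`` flag: ``I`` iff its absolute error beats the
        additive baseline's (ties → ``A``).
        """
        wt_value, single_map = self.model.training_singles()
        if genotypes is None:
            pairs = [
                (g, a, i)
                for g, a, i in zip(
                    self.model.genotypes, self.model.endog, self.model.ids
                )
                if len(g) >= 2
            ]
            if not pairs:
                raise ValueError("no multi-point mutants to analyse")
            genotypes = [p[0] for p in pairs]
            observed = [p[1] for p in pairs]
            ids = [p[2] for p in pairs]
        elif observed is None:
            raise ValueError("observed activities required with explicit genotypes")
        predictions = {model_name: self.predict_genotypes(genotypes)}
        for name, res in (extra_models or {}).items():
            predictions[name] = res.predict_genotypes(genotypes)
        records = build_epistasis_records(
            genotypes,
            observed,
            wt_value,
            single_map,
            model_predictions=predictions,
            tol=tol,
            ids=ids,
        )
        return epistasis_table(records)

    def additive_baseline(self, genotypes: Sequence[Genotype]) -> np.ndarray:
        """Additive-theoretical activity for each genotype."""
        wt_value, single_map = self.model.training_singles()
        return np.array(
            [additive_prediction(g, wt_value, single_map) for g in genotypes]
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit and its validation."""
        m = self.model
        lines = [
            "Spectral sequence-activity model",
            "=" * 48,
            f"{'No. variants:':<28}{len(m.endog)}",
            f"{'Encoding index:':<28}{m.index.accession}",
            f"{'Mode:':<28}{m.mode}",
            f"{'Energy definition:':<28}{m.energy}",
            f"{'Features:':<28}{m.exog.n_features}",
            f"{'PLS components:':<28}{self.n_components}",
            f"{'Activity unit:':<28}{m.activity_unit}",
            "-" * 48,
            f"{'CV scheme:':<28}{self.cv.scheme}",
            f"{'CV R^2 (sq. Pearson):':<28}{self.loocv_r2:.4f}",
            f"{'CV R^2 (1 - SSE/SST):':<28}{self.cv.r2_residual:.4f}",
            f"{'CV RMSE:':<28}{self.loocv_rmse:.4f}",
            f"{'Full-set R^2:':<28}{self.full_set_r2:.4f}",
            f"{'Full-set RMSE:':<28}{self.full_set_rmse:.4f}",
            "=" * 48,
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model (JSON): encoding + PLS vectors + CV."""
        payload = {
            "software_version": _version,
            "pls": self.pls.to_dict(),
            "encoding": {
                "index_accession": self.model.index.accession,
                "index_description": self.model.index.description,
                "index_values": dict(self.model.index.values),
                "mode": self.model.mode,
                "pad_to": self.model.pad_to,
                "energy": self.model.energy,
                "scale": self.model.scale,
            },
            "activity_unit": self.model.activity_unit,
            "thermo": {"R": self.model.thermo.R, "T": self.model.thermo.T},
            "wt_sequence": self.model.wt_sequence,
            "training": {
                "ids": self.model.ids,
                "activities": self.model.endog.tolist(),
                "genotypes": [
                    format_genotype(g) for g in (self.model.genotypes or [])
                ]
                or None,
            },
            "cv": {
                "scheme": self.cv.scheme,
                "r2": self.cv.r2,
                "rmse": self.cv.rmse,
                "full_set_r2": self.cv.full_set_r2,
                "full_set_rmse": self.cv.full_set_rmse,
                "n_components": self.cv.n_components,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "SequenceActivityResults":
        """Rebuild a results object from :meth:`save` output."""
        payload = json.loads(Path(path).read_text())
        enc = payload["encoding"]
        index = EncodingIndex(
            accession=enc["index_accession"],
            description=enc.get("index_description", ""),
            values=enc["index_values"],
        )
        training = payload["training"]
        wt = payload.get("wt_sequence")
        genotypes = None
        if training.get("genotypes") is not None:
            genotypes = [parse_genotype(g, wt) for g in training["genotypes"]]
            sequences = [apply_genotype(wt, g) for g in genotypes]
        else:
            raise ValueError("stored model lacks genotypes; cannot rebuild sequences")
        thermo = ThermoParams(**payload.get("thermo", {}))
        model = SequenceActivityModel(
            training["activities"],
            sequences,
            ids=training["ids"],
            index=index,
            mode=enc["mode"],
            pad_to=enc.get("pad_to"),
            energy=enc.get("energy", "squared"),
            scale=enc.get("scale", False),
            activity_unit=payload["activity_unit"],
            wt_sequence=wt,
            genotypes=genotypes,
            thermo=thermo,
        )
        pls = PLSModel.from_dict(payload["pls"])
        pls.fitted_values = predict(pls, model.exog)
        n = len(model.endog)
        cv_components = min(payload["cv"]["n_components"], n - 2, model.exog.n_features)
        cv = cross_validate(
            model.exog,
            model.endog,
            n_components=max(cv_components, 1),
            scheme="loocv",
            scale=model.scale,
        )
        full = PredictionSet(y=model.endog, y_hat=pls.fitted_values, ids=tuple(model.ids))
        cv = replace(cv, full_set_r2=r_squared(full), full_set_rmse=rmse(full))
        return SequenceActivityResults(model, pls, cv)
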