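"""statsmodels-style front end for the association pipeline.

``AssociationModel.from_dataframe(table, families)`` holds the cohort
and configuration; ``fit()`` runs the full ledger (zero-variance
pruning, Spearman screen, shadow-feature importance, retention,
family-dispatched univariable GLMs, multivariable models, bagged
bootstrap estimates) and returns an :class:`AssociationResults` whose
``report`` carries the significant associations, the full unfiltered
univariable table, and a provenance block sufficient to reproduce every
number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cordmotor.association.glm import BaggedEstimate, GLMResult, bagged_fit, fit_glm, multivariable_model
from cordmotor.association.screen import (
    BorutaResult,
    boruta_select,
    drop_zero_variance,
    retain_variables,
    spearman_screen,
)

__all__ = [
    "AssociationConfig",
    "AssociationModel",
    "AssociationResults",
    "AssociationReport",
    "build_report",
]

REPORT_COLUMNS = ["motor_var", "mri_var", "family", "estimate", "se", "p", "n", "B"]


@dataclass
class AssociationConfig:
    """Thresholds and sizes of the screening/regression procedure.

    alpha : significance level for correlation flags, predictor
        selection and the final report (no multiplicity correction by
        default, matching the correlational scope; set
        ``bh_correction=True`` for Benjamini-Hochberg on the final
        p-values).
    rho_min : minimum |Spearman rho| for the "correlated" flag.
    boruta_* : shadow-feature selector sizes (0 iterations disables it).
    B : bootstrap copies for bagging (1,000 by default).
    """

    alpha: float = 0.05
    rho_min: float = 0.4
    boruta_iter: int = 100
    boruta_alpha: float = 0.01
    boruta_trees: int = 100
    B: int = 1000
    bh_correction: bool = False
    seed: int = 0


@dataclass
class AssociationReport:
    """Tidy significant table + full table + provenance."""

    significant: pd.DataFrame
    full: pd.DataFrame
    provenance: dict

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.significant.to_csv(directory / "report_significant.csv", index=False)
        self.full.to_csv(directory / "report_full.csv", index=False)
        prov = pd.Series(self.provenance, dtype=object)
        prov.to_csv(directory / "report_provenance.csv", header=["value"], index_label="key")

    @classmethod
    def from_csv(cls, directory) -> "AssociationReport":
        directory = Path(directory)
        significant = pd.read_csv(directory / "report_significant.csv")
        full = pd.read_csv(directory / "report_full.csv")
        if "flags" in full.columns:
            full["flags"] = full["flags"].fillna("")
        prov = pd.read_csv(directory / "report_provenance.csv", index_col="key")["value"].to_dict()
        return cls(significant=significant, full=full, provenance=prov)


class AssociationModel:
    """Cohort table + configuration, ready to fit.

    Parameters
    ----------
    table : cohort rows (subjects) by columns; MRI predictor columns and
        motor outcome columns.
    families : mapping of motor column -> family tag
        (``continuous`` | ``count`` | ``binary``).
    mri_vars, motor_vars : column subsets; by default inferred from the
        ``mri_*`` / ``motor_*`` naming convention.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        families: dict[str, str],
        mri_vars: list[str] | None = None,
        motor_vars: list[str] | None = None,
        config: AssociationConfig | None = None,
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.families = dict(families)
        self.mri_vars = mri_vars or [c for c in table.columns if c.startswith("mri_")]
        self.motor_vars = motor_vars or [c for c in table.columns if c.startswith("motor_")]
        if not self.mri_vars or not self.motor_vars:
            raise ValueError("need at least one MRI and one motor column")
        missing = [c for c in self.motor_vars if c not in self.families]
        if missing:
            raise ValueError(f"no family declared for motor columns: {missing}")
        self.config = config or AssociationConfig()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, families: dict[str, str], **kwargs) -> "AssociationModel":
        return cls(table, families, **kwargs)

    def fit(self, seed: int | None = None) -> "AssociationResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)

        # 1. zero-variance pruning over both variable blocks
        cols = self.mri_vars + self.motor_vars
        pruned, dropped = drop_zero_variance(self.table[cols], cols)
        mri = [c for c in self.mri_vars if c not in dropped]
        motor = [c for c in self.motor_vars if c not in dropped]
        if not mri or not motor:
            raise ValueError("zero-variance pruning removed an entire variable block")

        # 2. Spearman screen + shadow-feature importance per motor outcome
        screen = spearman_screen(pruned, mri, motor, cfg.alpha, cfg.rho_min)
        boruta: dict[str, BorutaResult] = {}
        if cfg.boruta_iter > 0 and len(mri) >= 2:
            for m in motor:
                boruta[m] = boruta_select(
                    pruned[mri],
                    pruned[m].to_numpy(),
                    family=self.families[m],
                    n_iter=cfg.boruta_iter,
                    alpha=cfg.boruta_alpha,
                    n_estimators=cfg.boruta_trees,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
        mri_kept, motor_kept = retain_variables(screen, boruta)

        # 3. univariable GLMs for every pair (full, unfiltered table)
        uni_rows = []
        univariable: dict[tuple[str, str], GLMResult] = {}
        for m in motor:
            fam = self.families[m]
            for x in mri:
                res = fit_glm(pruned[m], pruned[[x]], fam)
                univariable[(x, m)] = res
                uni_rows.append(
                    {
                        "motor_var": m,
                        "mri_var": x,
                        "family": res.family,
                        "estimate": res.params.get(x, np.nan),
                        "se": res.bse.get(x, np.nan),
                        "p": res.pvalues.get(x, np.nan),
                        "n": res.nobs,
                        "flags": ";".join(res.flags),
                    }
                )
        uni_table = pd.DataFrame(uni_rows)

        # 4. multivariable + bagged models per retained motor outcome
        multivariable: dict[str, GLMResult] = {}
        bagged: dict[str, BaggedEstimate] = {}
        for m in motor_kept:
            fam = self.families[m]
            significant_x = [
                x
                for x in mri_kept
                if np.isfinite(univariable[(x, m)].pvalues.get(x, np.nan))
                and univariable[(x, m)].pvalues[x] < cfg.alpha
            ]
            if not significant_x:
                continue
            multivariable[m] = multivariable_model(pruned[m], pruned[significant_x], fam)
            bagged[m] = bagged_fit(
                pruned[m],
                pruned[significant_x],
                fam,
                B=cfg.B,
                seed=int(rng.integers(0, 2**31 - 1)),
            )

        report = build_report(
            bagged,
            self.families,
            uni_table,
            alpha=cfg.alpha,
            bh_correction=cfg.bh_correction,
            provenance={
                "seed": seed,
                "alpha": cfg.alpha,
                "rho_min": cfg.rho_min,
                "boruta_iter": cfg.boruta_iter,
                "boruta_alpha": cfg.boruta_alpha,
                "boruta_trees": cfg.boruta_trees,
                "B": cfg.B,
                "bh_correction": cfg.bh_correction,
                "n_subjects": len(pruned),
                "dropped_zero_variance": ";".join(dropped),
                "mri_kept": ";".join(mri_kept),
                "motor_kept": ";".join(motor_kept),
            },
        )
        return AssociationResults(
            model=self,
            dropped=dropped,
            screening=screen,
            boruta=boruta,
            mri_kept=mri_kept,
            motor_kept=motor_kept,
            univariable=uni_table,
            multivariable=multivariable,
            bagged=bagged,
            report=report,
        )


def build_report(
    bagged: dict[str, BaggedEstimate],
    families: dict[str, str],
    uni_table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correction: bool = False,
    provenance: dict | None = None,
) -> AssociationReport:
    """Assemble the tidy report from the bagged fits.

    One row per (motor outcome, MRI predictor) coefficient of the bagged
    multivariable models: ensemble-mean adjusted estimate, ensemble SD
    as SE, normal-approximation p. The significant table keeps rows with
    p < alpha (after optional Benjamini-Hochberg); the full univariable
    table rides along unfiltered.
    """
    rows = []
    for m, est in bagged.items():
        for x in est.params.index:
            if x == "const":
                continue
            rows.append(
                {
                    "motor_var": m,
                    "mri_var": x,
                    "family": est.family,
                    "estimate": est.params[x],
                    "se": est.bse[x],
                    "p": est.pvalues[x],
                    "n": np.nan,
                    "B": est.B,
                }
            )
    adjusted = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(adjusted) and bh_correction:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(adjusted["p"])
        p_adj = adjusted["p"].to_numpy(copy=True)
        if ok.any():
            p_adj[ok.to_numpy()] = multipletests(adjusted.loc[ok, "p"], method="fdr_bh")[1]
        adjusted["p_adjusted"] = p_adj
        sig = adjusted[adjusted["p_adjusted"] < alpha].reset_index(drop=True)
    else:
        sig = adjusted[adjusted["p"] < alpha].reset_index(drop=True)
    return AssociationReport(
        significant=sig,
        full=uni_table.copy(),
        provenance=provenance or {},
    )


@dataclass
class AssociationResults:
    """Everything the fitted pipeline produced, with a text summary."""

    model: AssociationModel
    dropped: list[str]
    screening: pd.DataFrame
    boruta: dict[str, BorutaResult]
    mri_kept: list[str]
    motor_kept: list[str]
    univariable: pd.DataFrame
    multivariable: dict[str, GLMResult]
    bagged: dict[str, BaggedEstimate]
    report: AssociationReport

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Association pipeline summary",
            "=" * 60,
            f"subjects: {len(self.model.table)}   alpha: {cfg.alpha}   B: {cfg.B}",
            f"zero-variance dropped: {', '.join(self.dropped) or 'none'}",
            f"MRI retained:   {', '.join(self.mri_kept) or 'none'}",
            f"motor retained: {', '.join(self.motor_kept) or 'none'}",
            "",
            "Significant associations (bagged adjusted estimates):",
        ]
        if len(self.report.significant):
            lines.append(
                self.report.significant[
                    ["motor_var", "mri_var", "family", "estimate", "se", "p"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        else:
            lines.append("  (none)")
        return "\n".join(lines)
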