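"""End-to-end orchestration: simulate -> geometry -> features -> delta ->
ICC -> signatures -> screening -> stability -> models -> evaluation.

Each stage persists its outputs (CSV/JSON) into a run directory together
with the config hash, and can reload prerequisites from disk, so the
pipeline can be driven stage-by-stage from the command line or run end to
end.  Synthetic volumes are never stored: they are a pure function of
(spec, subject) and are regenerated on demand, which keeps reruns
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import geometry, icc, markers, radiomics, signatures, synthetic
from .evaluation import (
    StabilitySelector,
    calibration_curve,
    classification_metrics,
    decision_curve,
    fit_combined_models,
)
from .volumes import ImageVolume, ROIMask

__all__ = ["RunConfig", "PipelineRun", "run_pipeline"]

log = logging.getLogger("deltazone")

STAGES = (
    "simulate", "zones", "features", "delta", "icc",
    "signature", "screen", "stability", "model", "evaluate",
)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips losslessly to YAML.

    Every stochastic stage has an explicit seed derived from ``seed``.
    """

    out_dir: str = "run"
    simulate: bool = True
    n_subjects: int = 40
    seed: int = 0
    train_fraction: float = 0.7
    rp_probability: float = 0.30
    location_effect: float = 8.0
    nlr4w_effect: float = 2.0
    texture_effect: dict[str, float] = field(default_factory=lambda: {"50-55": 2.0})
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 3.0)
    feature_classes: tuple[str, ...] = radiomics.ALL_CLASSES
    bin_width: float = 25.0
    normalize_scale: float = 100.0
    include_shape_in_delta: bool = False
    icc_threshold: float = 0.8
    icc_n_subjects: int = 40
    screening_alpha: float = 0.1
    cv_folds: int = 10
    n_lambdas: int = 50
    lambda_rule: str = "min"
    marker_change: str = "difference"
    top_k: int = 3
    register: bool = False
    min_zone_volume_cm3: float = 0.5

    def phantom_spec(self) -> synthetic.PhantomSpec:
        return synthetic.PhantomSpec(
            grid_shape=tuple(self.grid_shape),
            spacing_mm=tuple(self.spacing_mm),
            texture_effect=dict(self.texture_effect),
            rp_probability=self.rp_probability,
            seed=self.seed,
        )

    def cohort_spec(self) -> synthetic.CohortSpec:
        return synthetic.CohortSpec(
            n_subjects=self.n_subjects,
            train_fraction=self.train_fraction,
            rp_probability=self.rp_probability,
            location_effect=self.location_effect,
            nlr4w_effect=self.nlr4w_effect,
            seed=self.seed,
        )

    def feature_config(self) -> radiomics.FeatureConfig:
        return radiomics.FeatureConfig(
            classes=tuple(self.feature_classes), bin_width=self.bin_width
        )

    def zone_scheme(self) -> geometry.DoseZoneScheme:
        return geometry.DoseZoneScheme(min_volume_cm3=self.min_zone_volume_cm3)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "spacing_mm", "feature_classes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def normalize_for_extraction(
    ct: ImageVolume, lung: ROIMask, scale: float = 100.0
) -> ImageVolume:
    """Z-normalize over the lung and rescale so a 25-unit bin width yields a
    useful number of grey levels (z-scores span only a few units)."""
    z = radiomics.znormalize(ct, lung)
    return z.with_data(z.data * scale)


class PipelineRun:
    """Stage-by-stage execution bound to a run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.dir = Path(config.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.dir / "config.yaml")
        self._setup_log()
        self._volume_cache: dict[str, tuple] = {}

    def _setup_log(self) -> None:
        handler = logging.FileHandler(self.dir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s [%(stage)s] %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        self._log_handler = handler

    def _log(self, stage: str, msg: str) -> None:
        log.info(msg, extra={"stage": stage})

    def _path(self, name: str) -> Path:
        return self.dir / name

    def _write_csv(self, df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df.attrs["config_hash"] = self.config.digest()
        with open(self._path(name), "w") as fh:
            fh.write(f"# config_hash={self.config.digest()}\n")
            df.to_csv(fh, index=False)

    def _read_csv(self, name: str) -> pd.DataFrame:
        p = self._path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"stage prerequisite missing: {name}; run earlier stages first"
            )
        return pd.read_csv(p, comment="#")

    # ---------------------------------------------------------------- stages

    def simulate(self) -> pd.DataFrame:
        cfg = self.config
        if not cfg.simulate:
            table = self._read_csv("cohort.csv")
            return table
        self._log("simulate", f"generating cohort n={cfg.n_subjects} seed={cfg.seed}")
        table = synthetic.generate_cohort_table(cfg.cohort_spec())
        self._write_csv(table, "cohort.csv")
        return table

    def _volumes(self, subject_id: str, rp: int):
        key = f"{subject_id}:{rp}"
        if key not in self._volume_cache:
            vols = synthetic.generate_phantom_pair(
                self.config.phantom_spec(), subject_id, rp
            )
            if self.config.register:
                ct1, ct2, dose, lung, ptv = vols
                t = geometry.rigid_register(ct2, ct1)
                ct2 = geometry.resample_to_grid(ct2, ct1, t)
                vols = (ct1, ct2, dose, lung, ptv)
            if len(self._volume_cache) > 4:
                self._volume_cache.clear()
            self._volume_cache[key] = vols
        return self._volume_cache[key]

    def _subject_zones(self, subject_id: str, rp: int):
        ct1, ct2, dose, lung, ptv = self._volumes(subject_id, rp)
        zones, dropped = geometry.build_dose_zone_rois(
            dose, lung, self.config.zone_scheme()
        )
        return ct1, ct2, dose, lung, ptv, zones, dropped

    def zones(self) -> pd.DataFrame:
        table = self._read_csv("cohort.csv")
        rows = []
        for _, s in table.iterrows():
            sid, rp = s["subject_id"], int(s["rp"])
            try:
                ct1, ct2, dose, lung, ptv, zones, dropped = self._subject_zones(sid, rp)
            except Exception as exc:
                raise RuntimeError(f"stage 'zones' failed for subject {sid}: {exc}") from exc
            dvh = geometry.dvh_metrics(dose, lung, ptv)
            rows.append(
                {
                    "subject_id": sid,
                    **dvh.as_dict(),
                    "n_zones": len(zones),
                    "dropped_zones": ";".join(dropped),
                }
            )
        df = pd.DataFrame(rows)
        self._write_csv(df, "dvh.csv")
        self._log("zones", f"zone ROIs + DVH for {len(df)} subjects")
        return df

    def _extract_subject(self, sid: str, rp: int) -> list[dict]:
        cfg = self.config
        ct1, ct2, dose, lung, ptv, zones, _ = self._subject_zones(sid, rp)
        out = []
        for tp, ct in (("CT1", ct1), ("CT2", ct2)):
            norm = normalize_for_extraction(ct, lung, cfg.normalize_scale)
            for zone in zones:
                fv = radiomics.extract_features(norm, zone, cfg.feature_config())
                out.append(
                    {
                        "subject_id": sid,
                        "zone": zone.zone_label,
                        "timepoint": tp,
                        **fv.values,
                    }
                )
        return out

    def features(self) -> pd.DataFrame:
        table = self._read_csv("cohort.csv")
        rows = []
        for _, s in table.iterrows():
            sid, rp = s["subject_id"], int(s["rp"])
            try:
                rows.extend(self._extract_subject(sid, rp))
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'features' failed for subject {sid}: {exc}"
                ) from exc
        df = pd.DataFrame(rows)
        self._write_csv(df, "features.csv")
        self._log(
            "features",
            f"extracted {df.shape[1] - 3} features x {len(df)} (subject, zone, timepoint) rows "
            f"(classes={','.join(self.config.feature_classes)}, "
            f"bin_width={self.config.bin_width})",
        )
        return df

    def delta(self) -> dict[str, pd.DataFrame]:
        feats = self._read_csv("features.csv")
        drop_shape = not self.config.include_shape_in_delta
        delta_by_zone: dict[str, pd.DataFrame] = {}
        feature_cols = [c for c in feats.columns if c not in ("subject_id", "zone", "timepoint")]
        if drop_shape:
            feature_cols = [c for c in feature_cols if not c.startswith("shape_")]
        for zone, g in feats.groupby("zone"):
            wide1 = g[g.timepoint == "CT1"].set_index("subject_id")[feature_cols]
            wide2 = g[g.timepoint == "CT2"].set_index("subject_id")[feature_cols]
            common = wide1.index.intersection(wide2.index)
            rf1 = wide1.loc[common]
            rf2 = wide2.loc[common]
            with np.errstate(divide="ignore", invalid="ignore"):
                d = (rf2 - rf1) / rf1 * 100.0
            d = d.mask(rf1.abs() < 1e-12)
            # features with missing values are excluded
            d = d.dropna(axis=1, how="any")
            d = d.loc[:, np.isfinite(d).all(axis=0)]
            delta_by_zone[zone] = d
            self._write_csv(d.reset_index(), f"delta_{zone}.csv")
        self._log("delta", f"delta tables for zones: {sorted(delta_by_zone)}")
        return delta_by_zone

    def _zone_labels(self) -> list[str]:
        feats = self._read_csv("features.csv")
        return sorted(feats["zone"].unique())

    def icc(self) -> dict[str, list[str]]:
        """Two-rater reproducibility filter: the second delineation is the
        dose-zone ROI dilated by one voxel (clipped to the lung), emulating
        an independent contour of the same zone."""
        cfg = self.config
        table = self._read_csv("cohort.csv")
        train = table[table["set"] == "train"]
        sub = train.head(min(cfg.icc_n_subjects, len(train)))
        rows_a, rows_b = [], []
        for _, s in sub.iterrows():
            sid, rp = s["subject_id"], int(s["rp"])
            ct1, ct2, dose, lung, ptv, zones, _ = self._subject_zones(sid, rp)
            norm = normalize_for_extraction(ct1, lung, cfg.normalize_scale)
            for zone in zones:
                dil = ndimage.binary_dilation(zone.data) & lung.data
                zone_b = ROIMask(dil, zone.spacing_mm, zone.origin_mm,
                                 zone_label=zone.zone_label)
                fa = radiomics.extract_features(norm, zone, cfg.feature_config())
                fb = radiomics.extract_features(norm, zone_b, cfg.feature_config())
                rows_a.append({"subject_id": sid, "zone": zone.zone_label, **fa.values})
                rows_b.append({"subject_id": sid, "zone": zone.zone_label, **fb.values})
        ta, tb = pd.DataFrame(rows_a), pd.DataFrame(rows_b)
        retained: dict[str, list[str]] = {}
        for zone in sorted(ta["zone"].unique()):
            a = ta[ta.zone == zone].set_index("subject_id").drop(columns="zone")
            b = tb[tb.zone == zone].set_index("subject_id").drop(columns="zone")
            retained[zone] = icc.icc_filter(a, b, cfg.icc_threshold)
        (self._path("icc_retained.json")).write_text(
            json.dumps({"config_hash": self.config.digest(), "retained": retained}, indent=2)
        )
        self._log(
            "icc",
            f"ICC(2,1) > {cfg.icc_threshold} on {len(sub)} subjects; "
            + "; ".join(f"{z}: {len(v)}" for z, v in sorted(retained.items())),
        )
        return retained

    def signature(self) -> pd.DataFrame:
        cfg = self.config
        table = self._read_csv("cohort.csv").set_index("subject_id")
        retained = json.loads(self._path("icc_retained.json").read_text())["retained"]
        train_ids = table.index[table["set"] == "train"]
        scores = pd.DataFrame(index=table.index)
        sig_info = {}
        for zone in self._zone_labels():
            d = self._read_csv(f"delta_{zone}.csv").set_index("subject_id")
            cols = [c for c in d.columns if c in set(retained.get(zone, []))]
            if not cols:
                self._log("signature", f"zone {zone}: no ICC-retained features")
                continue
            X = d.loc[d.index.intersection(train_ids), cols]
            y = table.loc[X.index, "rp"].to_numpy()
            if len(np.unique(y)) < 2:
                raise RuntimeError(f"stage 'signature' zone {zone}: single-class training data")
            folds = min(cfg.cv_folds, int(np.bincount(y).min()))
            lasso = signatures.LassoSignature(
                n_folds=max(2, folds), n_lambdas=cfg.n_lambdas,
                lambda_rule=cfg.lambda_rule, random_state=cfg.seed,
            ).fit(X.to_numpy(float), y)
            sig = lasso.to_signature(cols, zone)
            if sig is None:
                self._log("signature", f"zone {zone}: penalty removed every feature")
                continue
            (self._path(f"signature_{zone}.json")).write_text(sig.to_json())
            scores.loc[d.index, f"RS_{zone}"] = signatures.score_signature(sig, d)
            sig_info[zone] = list(sig.feature_names)
        self._log(
            "signature",
            f"signatures (lambda rule={cfg.lambda_rule}): "
            + "; ".join(f"{z}: {len(v)} features" for z, v in sorted(sig_info.items())),
        )
        out = scores.reset_index()
        self._write_csv(out, "rs_scores.csv")
        return out

    def _assemble_model_table(self) -> pd.DataFrame:
        table = self._read_csv("cohort.csv")
        dvh = self._read_csv("dvh.csv")
        rs = self._read_csv("rs_scores.csv")
        mk = markers.compute_markers(
            table.set_index("subject_id"), change=self.config.marker_change
        ).reset_index()
        df = table.merge(dvh.drop(columns=["n_zones", "dropped_zones"]), on="subject_id")
        df = df.merge(rs, on="subject_id").merge(mk, on="subject_id")
        df["location_ml"] = (df["location"] == "middle_lower").astype(int)
        return df

    def screen(self) -> pd.DataFrame:
        df = self._assemble_model_table()
        train = df[df["set"] == "train"]
        rs_cols = [c for c in df.columns if c.startswith("RS_")]
        best_rs = self._best_zone(df, rs_cols)
        candidates = (
            ["location", "comorbidity", "MLD_Gy", "V5", "V20", "V30", "V40",
             "PTV_LV_ratio"]
            + ([best_rs] if best_rs else [])
            + [c for c in df.columns
               if any(c.startswith(m + "_") for m in markers.MARKERS)]
        )
        report = markers.univariate_screen(
            train, outcome="rp", alpha=self.config.screening_alpha,
            variables=candidates,
        )
        self._write_csv(report, "screening.csv")
        self._log(
            "screen",
            f"alpha={self.config.screening_alpha}: "
            f"{int(report.selected.sum())}/{len(report)} selected "
            f"(best zone signature: {best_rs})",
        )
        return report

    def _best_zone(self, df: pd.DataFrame, rs_cols: list[str]) -> str | None:
        """Zone signature with the top validation AUC."""
        valid = df[df["set"] == "valid"]
        best, best_auc = None, -np.inf
        for c in rs_cols:
            col = valid[c]
            if col.isna().any() or valid["rp"].nunique() < 2:
                continue
            auc = signatures.roc_auc(col.to_numpy(float), valid["rp"].to_numpy()).auc
            if auc > best_auc:
                best, best_auc = c, auc
        return best

    def stability(self) -> list[str]:
        df = self._assemble_model_table()
        report = self._read_csv("screening.csv")
        survivors = [
            v for v in report[report.selected == True]["variable"]  # noqa: E712
        ]
        train = df[df["set"] == "train"]
        cols = []
        for v in survivors:
            if v == "location":
                cols.append("location_ml")
            elif pd.api.types.is_numeric_dtype(train[v]):
                cols.append(v)
        X = train[cols].rename(columns={"location_ml": "location"}).fillna(0.0)
        sel = StabilitySelector(
            n_folds=min(self.config.cv_folds, int(train["rp"].value_counts().min())),
            top_k=self.config.top_k,
            random_state=self.config.seed,
        ).fit(X, train["rp"].to_numpy())
        (self._path("stability.json")).write_text(
            json.dumps(
                {
                    "config_hash": self.config.digest(),
                    "mean_rank": sel.mean_rank_.to_dict(),
                    "top_k": sel.top_k_,
                },
                indent=2,
            )
        )
        self._log("stability", f"top-{self.config.top_k}: {sel.top_k_}")
        return sel.top_k_

    def model(self) -> dict:
        df = self._assemble_model_table()
        top = json.loads(self._path("stability.json").read_text())["top_k"]
        top = [("location_ml" if t == "location" else t) for t in top]
        specs = {
            f"model{i}": top[: i] for i in range(1, len(top) + 1)
        }
        train = df[df["set"] == "train"].dropna(subset=top)
        models = fit_combined_models(
            train, specs, outcome="rp",
            n_folds=min(self.config.cv_folds, int(train["rp"].value_counts().min())),
            random_state=self.config.seed,
        )
        coefs = {
            name: {
                "columns": specs[name],
                "intercept": m.intercept_,
                "coef": m.coef_.tolist(),
                "alpha": m.alpha_,
            }
            for name, m in models.items()
        }
        (self._path("models.json")).write_text(
            json.dumps({"config_hash": self.config.digest(), "models": coefs}, indent=2)
        )
        self._log("model", f"fitted nested models: {list(specs)}")
        return coefs

    def evaluate(self) -> pd.DataFrame:
        df = self._assemble_model_table()
        info = json.loads(self._path("models.json").read_text())["models"]
        rows = []
        dca_frames = []
        valid_probs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, m in info.items():
            cols = m["columns"]
            sub = df.dropna(subset=cols)
            X = sub[cols].to_numpy(float)
            eta = X @ np.asarray(m["coef"]) + m["intercept"]
            probs = 1.0 / (1.0 + np.exp(-eta))
            is_train = (sub["set"] == "train").to_numpy()
            y = sub["rp"].to_numpy()
            rep_tr = classification_metrics(probs[is_train], y[is_train])
            rep_va = classification_metrics(
                probs[~is_train], y[~is_train], threshold=rep_tr.threshold
            )
            for split, rep in (("train", rep_tr), ("valid", rep_va)):
                rows.append({"model": name, "split": split, **rep.as_dict(),
                             "threshold": rep.threshold})
            dca = decision_curve(probs[~is_train], y[~is_train])
            dca.insert(0, "model", name)
            dca_frames.append(dca)
            valid_probs[name] = (probs[~is_train], y[~is_train])
            if name == list(info)[-1]:
                points, intercept, slope = calibration_curve(
                    probs[~is_train], y[~is_train],
                    n_bins=min(10, max(2, (~is_train).sum() // 4)),
                )
                self._write_csv(points.assign(recal_intercept=intercept,
                                              recal_slope=slope),
                                "calibration_valid.csv")
                self._plot_calibration(points)
        metrics = pd.DataFrame(rows)
        self._write_csv(metrics, "metrics.csv")
        dca_all = pd.concat(dca_frames, ignore_index=True)
        self._write_csv(dca_all, "dca_valid.csv")
        self._plot_dca(dca_all, y[~is_train].mean())
        self._write_csv(self._delong_pairs(valid_probs), "delong_valid.csv")
        self._log("evaluate", f"metrics written for models: {list(info)}")
        return metrics

    @staticmethod
    def _delong_pairs(valid_probs: dict) -> pd.DataFrame:
        """Paired DeLong comparisons of validation AUCs between models."""
        import itertools

        rows = []
        for (na, (pa, ya)), (nb, (pb, yb)) in itertools.combinations(
            valid_probs.items(), 2
        ):
            if len(pa) != len(pb) or np.unique(ya).size < 2:
                continue
            z, p = signatures.delong_test(pa, pb, ya)
            rows.append({"model_a": na, "model_b": nb, "z": z, "p": p})
        return pd.DataFrame(rows, columns=["model_a", "model_b", "z", "p"])

    def _plot_calibration(self, points: pd.DataFrame) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.plot([0, 1], [0, 1], "k--", lw=1, label="ideal")
        ax.plot(points["mean_predicted"], points["observed"], "o-",
                label="model")
        ax.set_xlabel("predicted risk")
        ax.set_ylabel("observed rate")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(self._path("calibration_valid.png"), dpi=120)
        plt.close(fig)

    def _plot_dca(self, dca: pd.DataFrame, prevalence: float) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for name, g in dca.groupby("model"):
            ax.plot(g["threshold"], g["nb_model"], label=name)
        g0 = dca[dca.model == dca.model.iloc[0]]
        ax.plot(g0["threshold"], g0["nb_all"], "k--", lw=1, label="treat all")
        ax.axhline(0.0, color="grey", lw=1, label="treat none")
        ax.set_ylim(-0.05, max(0.05, prevalence + 0.05))
        ax.set_xlabel("threshold probability")
        ax.set_ylabel("net benefit")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(self._path("dca_valid.png"), dpi=120)
        plt.close(fig)

    def run_all(self) -> pd.DataFrame:
        self.simulate()
        self.zones()
        self.features()
        self.delta()
        self.icc()
        self.signature()
        self.screen()
        self.stability()
        self.model()
        metrics = self.evaluate()
        self._log("run-all", "pipeline complete")
        return metrics

    def close(self) -> None:
        log.removeHandler(self._log_handler)
        self._log_handler.close()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every stage in order; returns the final metrics table."""
    run = PipelineRun(config)
    try:
        return run.run_all()
    finally:
        run.close()
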