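"""Readers/writers for the plain-text exchange formats and the study runner.

Spot tables are tab-delimited, clinical annotations CSV, matrices TSV with
samples as rows, fits and run manifests JSON, and configurations YAML.  The
``run_study`` entry point binds the pipeline stages into the three study
designs (pivotal, training, risk assessment) and writes a manifest recording
every effective parameter, seed and output hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker, diffexp, synthetic_data, unsupervised
from .diffexp import GLEASON_ORDER, PTNM_ORDER
from .normalize import NormalizeConfig, NormalizedMatrix, run_normalization
from .synthetic_data import SPOT_COLUMNS

logger = logging.getLogger(__name__)

_CHANNELS = {"antibody", "total_protein", "negative_control"}
_ANNOTATION_COLUMNS = ["sample_id", "group", "psa_ng_ml", "gleason", "ptnm",
                       "recurrent", "followup_years"]


def read_spot_table(path) -> pd.DataFrame:
    """Read and validate a tab-delimited spot table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} missing column(s): {missing}")
    if df.empty:
        logger.warning("spot table %s is empty", path)
        return pd.DataFrame(columns=SPOT_COLUMNS)
    out = df[SPOT_COLUMNS].copy()
    for col in ("print_conc_mg_ml", "raw_intensity", "local_background"):
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any():
            row = int(np.where(vals.isna())[0][0]) + 2  # 1-based incl. header
            raise ValueError(f"non-numeric {col} at line {row} of {path}")
        out[col] = vals
    reps = pd.to_numeric(out["replicate_idx"], errors="coerce")
    if reps.isna().any():
        row = int(np.where(reps.isna())[0][0]) + 2
        raise ValueError(f"non-numeric replicate_idx at line {row} of {path}")
    out["replicate_idx"] = reps.astype(int)
    bad_channel = ~out["channel"].isin(_CHANNELS)
    if bad_channel.any():
        raise ValueError(f"unknown channel value {out.loc[bad_channel, 'channel'].iloc[0]!r}")
    counts = out["channel"].value_counts().to_dict()
    logger.info("read %d spots from %s (%s)", len(out), path, counts)
    return out


def write_spot_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotation(path, extra_groups: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read and type-check a clinical annotation CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} missing column(s): {missing}")
    out = df[_ANNOTATION_COLUMNS].copy()
    for i, row in out.iterrows():
        line = i + 2
        if row["gleason"] and row["gleason"] not in GLEASON_ORDER:
            raise ValueError(f"malformed Gleason {row['gleason']!r} at line {line} of {path}")
        if row["ptnm"] and row["ptnm"] not in PTNM_ORDER:
            raise ValueError(f"pTNM {row['ptnm']!r} outside declared ordering at line {line} of {path}")
    psa = pd.to_numeric(out["psa_ng_ml"].mask(out["psa_ng_ml"] == ""), errors="coerce")
    malformed = psa.isna() & (out["psa_ng_ml"] != "")
    if malformed.any():
        line = int(np.where(malformed)[0][0]) + 2
        raise ValueError(f"malformed PSA value at line {line} of {path}")
    out["psa_ng_ml"] = psa
    out["recurrent"] = pd.to_numeric(out["recurrent"].mask(out["recurrent"] == ""), errors="coerce")
    out["followup_years"] = pd.to_numeric(
        out["followup_years"].mask(out["followup_years"] == ""), errors="coerce"
    )
    return out


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)


def write_matrix(matrix: NormalizedMatrix, path, provenance_path=None) -> None:
    matrix.values.to_csv(path, sep="\t")
    if provenance_path is not None:
        Path(provenance_path).write_text(json.dumps(matrix.provenance, indent=2))


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_PRESETS = {"pivotal": synthetic_data.pivotal_cohort,
            "training": synthetic_data.training_cohort,
            "risk": synthetic_data.risk_cohort}

_KNOWN_KEYS = {"preset", "seed", "out_dir", "alpha", "test", "print_conc",
               "noise_cv", "signature_k", "spots", "annotation"}


def run_study(config: dict) -> dict:
    """Execute a preset study design end to end and write a manifest.

    Config keys: ``preset`` (pivotal|training|risk), ``seed``, ``out_dir``,
    optional ``alpha``, ``test``, ``print_conc``, ``noise_cv``,
    ``signature_k``, and optional pre-existing ``spots``/``annotation`` paths
    (otherwise the synthetic generator produces them).  Unknown keys are
    rejected.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    preset = config.get("preset", "pivotal")
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    out_dir = Path(config.get("out_dir", "evrppa_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    gen_kwargs = {"seed": seed}
    if "noise_cv" in config:
        gen_kwargs["noise_cv"] = float(config["noise_cv"])
    layout, cohort = _PRESETS[preset](**gen_kwargs)

    stage = "simulate"
    try:
        if "spots" in config:
            spots = read_spot_table(config["spots"])
        else:
            spots = synthetic_data.generate_slide(layout, cohort)
            write_spot_table(spots, out_dir / "spots.tsv")
        if "annotation" in config:
            annotation = read_annotation(config["annotation"])
        else:
            rec = {"Recurrent": 1.0, "Advanced": 1.0, "NonRecurrent": 0.0} \
                if preset == "risk" else None
            annotation = synthetic_data.generate_annotation(cohort, recurrent_fraction=rec)
            write_annotation(annotation, out_dir / "annotation.csv")

        stage = "normalize"
        ncfg = NormalizeConfig(print_conc=config.get("print_conc"))
        matrix = run_normalization(spots, ncfg)
        write_matrix(matrix, out_dir / "matrix.tsv", out_dir / "matrix_provenance.json")

        stage = "diffexp"
        default_test = "wilcoxon" if preset == "risk" else "t"
        test = config.get("test", default_test)
        comparisons = _preset_comparisons(preset)
        diff_outputs = {}
        sig_sets = {}
        for a, b in comparisons:
            res = diffexp.compare_groups(matrix.values, annotation, a, b, test=test, alpha=alpha)
            frame = diffexp.results_to_frame(res)
            name = f"diffexp_{a}_vs_{b}.tsv"
            frame.to_csv(out_dir / name, sep="\t", index=False)
            diff_outputs[f"{a}_vs_{b}"] = name
            sig_sets[f"{a}_vs_{b}"] = {r.endpoint for r in res if r.significant}
        if len(sig_sets) >= 2:
            inter = diffexp.comparison_intersections(sig_sets)
            inter.to_csv(out_dir / "intersections.tsv", sep="\t", index=False)

        stage = "unsupervised"
        complete = matrix.values.dropna(axis=1)
        pca = unsupervised.pca_covariance(complete)
        pca.scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t")
        clust = unsupervised.hierarchical_cluster(complete)
        (out_dir / "row_tree.nwk").write_text(
            unsupervised.linkage_to_newick(clust.row_linkage, list(complete.index))
        )
        (out_dir / "col_tree.nwk").write_text(
            unsupervised.linkage_to_newick(clust.col_linkage, list(complete.columns))
        )

        stage = "biomarker"
        notices = []
        roc_rows = []
        case_group, control_groups = _preset_case_control(preset)
        groups = annotation.set_index("sample_id")["group"]
        mask = matrix.values.index.map(
            lambda s: groups.get(s) in {case_group, *control_groups}
        )
        sub = matrix.values[mask]
        labels = np.asarray(
            [1 if groups[s] == case_group else 0 for s in sub.index], dtype=int
        )
        if preset == "risk":
            rec_labels = annotation.set_index("sample_id")["recurrent"]
            have_rec = rec_labels.notna().any()
            if not have_rec:
                notices.append("prognostic stage skipped: no recurrence labels")
                labels = None
        if labels is not None and labels.sum() >= 2 and (labels == 0).sum() >= 2:
            for ep in sub.columns:
                vals = sub[ep].to_numpy(dtype=float)
                if np.isfinite(vals).sum() < 4:
                    continue
                roc_rows.append(biomarker.roc_analysis(vals, labels, endpoint=ep))
            roc_frame = pd.DataFrame([r.__dict__ for r in roc_rows])
            roc_frame.to_csv(out_dir / "roc.tsv", sep="\t", index=False)
            if preset == "risk":
                k = int(config.get("signature_k", 3))
                eps = [e for e in synthetic_data.PROGNOSTIC_ENDPOINTS if e in sub.columns]
                if len(eps) >= k:
                    sig = biomarker.signature_from_matrix(sub, eps, labels, k=k)
                    roc, confusion = biomarker.evaluate_signature(sub, sig, labels)
                    write_json(
                        {"signature": sig, "roc": roc, "confusion": confusion},
                        out_dir / "signature.json",
                    )
    except Exception as err:
        raise RuntimeError(f"study stage {stage!r} failed: {err}") from err

    outputs = sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json")
    manifest = {
        "preset": preset,
        "seed": seed,
        "parameters": {
            "alpha": alpha,
            "test": test,
            "print_conc": matrix.provenance["print_conc_mg_ml"],
            "noise_cv": cohort.noise_cv,
            "normalization": matrix.provenance["config"],
        },
        "notices": notices,
        "outputs": {name: _sha256(out_dir / name) for name in outputs},
    }
    write_json(manifest, out_dir / "manifest.json")
    return manifest


def _preset_comparisons(preset: str) -> list[tuple[str, str]]:
    if preset == "pivotal":
        return [("PCa", "HD")]
    if preset == "training":
        return [("PCa", "HD"), ("PCa", "Hyper"), ("PCa", "DF")]
    return [("Recurrent", "NonRecurrent"), ("Advanced", "NonRecurrent")]


def _preset_case_control(preset: str) -> tuple[str, list[str]]:
    if preset == "pivotal":
        return "PCa", ["HD"]
    if preset == "training":
        return "PCa", ["HD", "Hyper"]
    return "Recurrent", ["NonRecurrent"]
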