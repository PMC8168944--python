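"""Readers/writers for cohort CSVs, model archives, reference tables, manifests.

The cohort lives in one long-format CSV: one row per subject-visit with
``subject_id``, ``time_years``, ``diagnosis`` and one column per feature,
named ``<modality>_<index-or-label>`` (``amy_0 ... amy_40``,
``cli_ADAS11 ... cli_CDRSB``).  An absent modality at a visit is a fully
empty block of cells; partially filled blocks are rejected.  Clinical scores
whose native polarity decreases with severity are sign-flipped on read (and
restored on write) so that in memory every feature increases with pathology.

Fitted models serialize to a single versioned JSON archive carrying the
schema, standardization statistics, encoder/decoder/dynamics parameters and
the training configuration; reloading reproduces the model exactly.  Every
CLI output is accompanied by a manifest (input hashes, seed, versions)
sufficient to regenerate it bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .inference import FittedModel, TrainingConfig
from .longterm import ReferenceTrajectory
from .observation import (
    DIAGNOSIS_LABELS,
    DecoderParams,
    EncoderParams,
    ModalitySchema,
    ObservationSet,
    Standardizer,
    Visit,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "schema_from_header",
    "load_generator_config",
    "save_model",
    "load_model",
    "write_reference",
    "read_reference",
    "write_manifest",
]

ARCHIVE_VERSION = 1


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def _apply_flips(schema: ModalitySchema, name: str, x: np.ndarray) -> np.ndarray:
    mask = schema.flip_mask(name)
    if mask.any():
        x = x.copy()
        x[..., mask] = -x[..., mask]
    return x


def write_cohort(cohort: list[ObservationSet], path, schema: ModalitySchema) -> None:
    """Write the long-format cohort CSV (native feature polarity)."""
    rows = []
    for s in cohort:
        for v in s.visits:
            row: dict = {"subject_id": s.subject_id, "time_years": v.time,
                         "diagnosis": v.diagnosis}
            for name in schema.names:
                cols = schema.columns(name)
                b = v.blocks.get(name)
                if b is None:
                    row.update({c: np.nan for c in cols})
                else:
                    native = _apply_flips(schema, name, np.asarray(b, dtype=float))
                    row.update(dict(zip(cols, native)))
            rows.append(row)
    # %.17g guarantees bit-exact float round-trips through the CSV
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path, schema: ModalitySchema) -> list[ObservationSet]:
    """Read and validate a cohort CSV into per-subject observation sets.

    Enforces the all-or-none rule per modality block, the diagnosis
    vocabulary and finite visit times; rows are ordered by subject then
    time.  The complete-visit requirement is checked lazily at fit time.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "time_years", "diagnosis"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort CSV must contain columns {sorted(required)}")
    for name in schema.names:
        missing_cols = [c for c in schema.columns(name) if c not in df.columns]
        if missing_cols:
            raise ValueError(f"cohort CSV lacks columns for block {name}: {missing_cols}")
    cohort = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("time_years", kind="stable")
        visits = []
        for _, row in g.iterrows():
            t = row["time_years"]
            if not np.isfinite(t):
                raise ValueError(f"subject {sid}: non-finite visit time {t!r}")
            dx = row["diagnosis"]
            if dx not in DIAGNOSIS_LABELS:
                raise ValueError(
                    f"subject {sid} t={t}: unknown diagnosis {dx!r}; "
                    f"allowed labels are {list(DIAGNOSIS_LABELS)}"
                )
            blocks: dict = {}
            for name in schema.names:
                vals = row[schema.columns(name)].to_numpy(dtype=float)
                n_present = int(np.sum(~np.isnan(vals)))
                if n_present == 0:
                    blocks[name] = None
                elif n_present == len(vals):
                    blocks[name] = _apply_flips(schema, name, vals)
                else:
                    raise ValueError(
                        f"subject {sid} t={t}: block {name} is partially filled "
                        "(modality blocks are all-or-none per visit)"
                    )
            visits.append(Visit(time=float(t), blocks=blocks, diagnosis=str(dx)))
        cohort.append(ObservationSet(subject_id=str(sid), visits=visits))
    return cohort


def schema_from_header(path, flips: tuple[str, ...] = ()) -> ModalitySchema:
    """Infer modality names/dims from a cohort CSV header (column order)."""
    cols = list(pd.read_csv(path, nrows=0).columns)
    names: list[str] = []
    dims: list[int] = []
    labels: list[tuple[str, ...]] = []
    for c in cols:
        if c in ("subject_id", "time_years", "diagnosis") or "_" not in c:
            continue
        name, lab = c.split("_", 1)
        if not names or names[-1] != name:
            names.append(name)
            dims.append(0)
            labels.append(())
        dims[-1] += 1
        labels[-1] = labels[-1] + (lab,)
    numeric = [all(l.isdigit() for l in labs) for labs in labels]
    feature_labels = tuple(None if num else labs for num, labs in zip(numeric, labels))
    if all(f is None for f in feature_labels):
        feature_labels = None
    return ModalitySchema(names=tuple(names), dims=tuple(dims),
                          feature_labels=feature_labels, flips=flips)


# ---------------------------------------------------------------------------
# generator configuration (YAML)
# ---------------------------------------------------------------------------

def load_generator_config(path):
    """Generator configuration from a YAML file of overrides.

    Every key maps to a :class:`~adcascade.synthetic.GeneratorConfig` field
    and overrides the canonical default (``full_dims`` selects the
    41/41/41/7 schema).  Unknown keys are rejected.
    """
    import yaml

    from .synthetic import canonical_config

    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("generator config must be a YAML mapping")
    config = canonical_config(
        full_dims=bool(doc.pop("full_dims", False)),
        n_subjects=int(doc.pop("n_subjects", 300)),
        seed=int(doc.pop("seed", 0)),
    )
    valid = {f.name for f in dataclasses.fields(config)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown generator-config keys: {sorted(unknown)}")
    overrides: dict = {}
    for key, val in doc.items():
        if key in ("W", "anchor_state"):
            overrides[key] = np.asarray(val, dtype=float)
        elif key in ("loadings", "offsets"):
            overrides[key] = {m: np.asarray(v, dtype=float) for m, v in val.items()}
        elif key in ("stage_thresholds", "visit_count_range"):
            overrides[key] = tuple(val)
        else:
            overrides[key] = val
    return dataclasses.replace(config, **overrides)


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def _arr(x):
    return np.asarray(x).tolist()


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model to the versioned JSON archive."""
    s = model.schema
    doc = {
        "format": "adcascade-model",
        "version": ARCHIVE_VERSION,
        "schema": {
            "names": list(s.names),
            "dims": list(s.dims),
            "feature_labels": None if s.feature_labels is None else [
                None if f is None else list(f) for f in s.feature_labels
            ],
            "flips": list(s.flips),
        },
        "standardizer": {
            "means": {m: _arr(model.standardizer.means[m]) for m in s.names},
            "sds": {m: _arr(model.standardizer.sds[m]) for m in s.names},
        },
        "encoder": {
            "weights": {m: _arr(model.encoder.weights[m]) for m in s.names},
            "biases": {m: float(model.encoder.biases[m]) for m in s.names},
            "log_scales": {m: float(model.encoder.log_scales[m]) for m in s.names},
            "squash": model.encoder.squash,
        },
        "decoder": {
            "loadings": {m: _arr(model.decoder.loadings[m]) for m in s.names},
            "offsets": {m: _arr(model.decoder.offsets[m]) for m in s.names},
            "log_sigma2": {m: float(model.decoder.log_sigma2[m]) for m in s.names},
            "link": model.decoder.link,
        },
        "dynamics": {"W": _arr(model.dynamics.W)},
        "training_config": dataclasses.asdict(model.config),
        "final_elbo": float(model.final_elbo),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> FittedModel:
    """Load a model archive; inverse of :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "adcascade-model":
        raise ValueError(f"{path} is not an adcascade model archive")
    if doc.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported archive version {doc.get('version')}")
    sc = doc["schema"]
    schema = ModalitySchema(
        names=tuple(sc["names"]),
        dims=tuple(sc["dims"]),
        feature_labels=None if sc["feature_labels"] is None else tuple(
            None if f is None else tuple(f) for f in sc["feature_labels"]
        ),
        flips=tuple(sc["flips"]),
    )
    std = Standardizer(
        means={m: np.asarray(v, dtype=float) for m, v in doc["standardizer"]["means"].items()},
        sds={m: np.asarray(v, dtype=float) for m, v in doc["standardizer"]["sds"].items()},
    )
    enc = EncoderParams(
        weights={m: np.asarray(v, dtype=float) for m, v in doc["encoder"]["weights"].items()},
        biases={m: float(v) for m, v in doc["encoder"]["biases"].items()},
        log_scales={m: float(v) for m, v in doc["encoder"]["log_scales"].items()},
        squash=doc["encoder"].get("squash", "linear"),
    )
    dec = DecoderParams(
        loadings={m: np.asarray(v, dtype=float) for m, v in doc["decoder"]["loadings"].items()},
        offsets={m: np.asarray(v, dtype=float) for m, v in doc["decoder"]["offsets"].items()},
        log_sigma2={m: float(v) for m, v in doc["decoder"]["log_sigma2"].items()},
        link=doc["decoder"]["link"],
    )
    return FittedModel(
        schema=schema,
        standardizer=std,
        encoder=enc,
        decoder=dec,
        dynamics=DynamicsParams(W=np.asarray(doc["dynamics"]["W"], dtype=float)),
        config=TrainingConfig(**doc["training_config"]),
        final_elbo=float(doc["final_elbo"]),
    )


# ---------------------------------------------------------------------------
# reference trajectory CSV
# ---------------------------------------------------------------------------

def write_reference(ref: ReferenceTrajectory, path, schema: ModalitySchema) -> None:
    cols = {"time": ref.times}
    for i, m in enumerate(schema.names):
        cols[f"mean_{m}"] = ref.mean[:, i]
        cols[f"sd_{m}"] = ref.sd[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_reference(path, schema: ModalitySchema) -> ReferenceTrajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    mean = np.stack([df[f"mean_{m}"].to_numpy() for m in schema.names], axis=1)
    sd = np.stack([df[f"sd_{m}"].to_numpy() for m in schema.names], axis=1)
    return ReferenceTrajectory(times=df["time"].to_numpy(), mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, command: str, seed: int | None,
                   inputs: dict | None = None, config: dict | None = None) -> Path:
    """Write ``manifest.json`` beside the outputs of a CLI run.

    Records the command, seed, configuration, input-file hashes and library
    versions: everything needed to regenerate the outputs bit-for-bit.
    """
    from . import __version__

    out_dir = Path(out_dir)
    doc = {
        "command": command,
        "seed": seed,
        "config": config or {},
        "inputs": {
            k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in (inputs or {}).items()
        },
        "versions": {"adcascade": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path
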