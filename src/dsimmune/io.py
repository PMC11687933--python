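"""Schema-validated table I/O, configuration, and pipeline orchestration.

Canonical on-disk dialect is TSV (tab-delimited, UTF-8, header row); CSV is
accepted on read.  Every table kind has a schema naming its required columns
and their semantic types; readers validate and coerce, writers emit tables
that re-read under the same schema.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_matrix",
    "write_matrix",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


@dataclass(frozen=True)
class TableSchema:
    kind: str
    required: dict  # column -> {"str","float","int","bool"}
    allow_extra: bool = False


SCHEMAS = {
    "participants": TableSchema(
        "participants",
        {"sample_id": "str", "karyotype": "str", "age": "float", "sex": "str"},
        allow_extra=True,  # condition flags and cohort tags
    ),
    "analytes": TableSchema(
        "analytes",
        {"sample_id": "str", "analyte": "str", "plate": "str", "source": "str",
         "well": "int", "value": "float", "flag": "str"},
    ),
    "analytes_collapsed": TableSchema(
        "analytes_collapsed",
        {"sample_id": "str", "analyte": "str", "plate": "str",
         "value": "float"},
        allow_extra=True,
    ),
    "frequencies": TableSchema(
        "frequencies",
        {"sample_id": "str", "level": "str", "cluster": "str",
         "proportion": "float"},
    ),
    "trial": TableSchema(
        "trial",
        {"participant_id": "str", "week": "int", "measurement": "str",
         "value": "float"},
        allow_extra=True,  # annotation flags
    ),
    "de_results": TableSchema(
        "de_results",
        {"gene": "str", "log2fc": "float", "q": "float"},
        allow_extra=True,
    ),
    "safety_log": TableSchema(
        "safety_log",
        {"participant_id": "str", "event": "str", "grade": "int",
         "attribution": "str", "serious": "bool"},
    ),
}

_COERCE = {
    "str": lambda s: s.astype(str),
    "float": lambda s: pd.to_numeric(s, errors="coerce").astype(float),
    "int": lambda s: pd.to_numeric(s, errors="coerce"),
    "bool": lambda s: s.map(
        {True: True, False: False, "True": True, "False": False,
         "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
    ),
}


def _sniff_sep(path: Path) -> str:
    head = Path(path).open("r", encoding="utf-8").readline()
    if "\t" in head:
        return "\t"
    if "," in head:
        return ","
    raise SchemaError(f"{path}: could not detect a tab or comma delimiter")


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV/CSV table and validate it against ``schema``.

    Missing required columns, unknown extras (when disallowed) and
    uncoercible values are reported with column names and row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = set(schema.required) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {sorted(missing)} "
            f"for schema {schema.kind!r}"
        )
    extras = set(df.columns) - set(schema.required)
    if extras and not schema.allow_extra:
        raise SchemaError(
            f"{path}: unexpected columns {sorted(extras)} for schema {schema.kind!r}"
        )
    for col, kind in schema.required.items():
        before_na = df[col].isna()
        coerced = _COERCE[kind](df[col])
        bad = coerced.isna() & ~before_na
        if kind in ("float", "int", "bool") and bad.any():
            rows = list(df.index[bad][:10])
            raise SchemaError(
                f"{path}: column {col!r} has non-{kind} values at rows {rows}"
            )
        if kind == "int":
            coerced = coerced.astype("Int64")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as canonical TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_matrix(path) -> pd.DataFrame:
    """Read a samples x features numeric matrix (first column = sample id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric matrix columns {non_numeric}")
    return df


def write_matrix(df: pd.DataFrame, path, index_name: str = "sample_id") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULT_PARAMS = {
    "seed": 0,
    "positivity_percentile": 0.90,
    "min_detected": 18,
    "min_cases": 5,
    "fdr": 0.1,
    "tpo_percentile": 0.95,
    "ana_cutoff": 2.1,
    "flag_threshold": 0.10,
    "score_mode": "reference",
    "uln": {"anti_TPO": 60.0, "anti_TG": 4.0},
    "max_definite_saes": 2,
    "log_level": "INFO",
}

_RANGES = {
    "positivity_percentile": (0.0, 1.0),
    "tpo_percentile": (0.0, 1.0),
    "fdr": (0.0, 1.0),
    "flag_threshold": (0.0, 1.0),
}


@dataclass(frozen=True)
class RunConfig:
    """Effective pipeline configuration (defaults filled)."""

    params: dict = field(default_factory=lambda: dict(_DEFAULT_PARAMS))

    def __getitem__(self, key):
        return self.params[key]

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a TOML run configuration, fill defaults, validate ranges."""
    params = json.loads(json.dumps(_DEFAULT_PARAMS))  # deep copy
    loaded = {}
    if path is not None:
        with open(path, "rb") as fh:
            loaded = tomllib.load(fh)
    for src in (loaded, overrides or {}):
        for k, v in src.items():
            if k == "uln":
                params["uln"].update(v)
            else:
                params[k] = v
    for key, (lo, hi) in _RANGES.items():
        v = params[key]
        if not (lo < v <= hi):
            raise ConfigurationError(
                f"{key}={v} out of range; permitted ({lo}, {hi}]"
            )
    if params["score_mode"] not in ("reference", "internal"):
        raise ConfigurationError("score_mode must be 'reference' or 'internal'")
    return RunConfig(params=params)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir, synth_config=None) -> Path:
    """Run the full synthetic pipeline and write every intermediate table.

    Stages: simulate -> autoantibody enrichment -> composite scores ->
    analyte differential abundance -> compositional analysis -> trial
    endpoints.  Emits a manifest (seed, config digest, timings) next to the
    result tables.
    """
    from . import autoab, composition, markers, scores, synth, trial as trial_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    if synth_config is None:
        synth_config = synth.default_config(seed=int(config["seed"]))
    bundle = synth.generate_cohort(synth_config)
    write_table(bundle.participants, out / "participants.tsv")
    write_matrix(bundle.antigen_array.mfi, out / "mfi.tsv")
    write_matrix(bundle.antigen_array.bead_count, out / "bead_count.tsv")
    write_table(bundle.analytes, out / "analytes.tsv")
    write_matrix(bundle.expression, out / "expression.tsv")
    write_table(bundle.de_results, out / "de_results.tsv")
    write_table(bundle.frequencies, out / "frequencies.tsv")
    write_table(bundle.trial, out / "trial.tsv")
    timings["simulate"] = time.time() - t0

    participants = bundle.participants
    controls = participants.loc[participants["karyotype"] == "D21", "sample_id"]

    t = time.time()
    mfi = autoab.qc_bead_counts(bundle.antigen_array.mfi,
                                bundle.antigen_array.bead_count)
    mad = autoab.mad_transform(mfi)
    calls = autoab.call_positivity(mad, controls,
                                   percentile=config["positivity_percentile"])
    calls = autoab.filter_detected(calls, min_samples=int(config["min_detected"]))
    enrich = autoab.fisher_enrichment(
        calls, participants.set_index("sample_id")["karyotype"])
    write_table(enrich, out / "autoab_enrichment.tsv")
    timings["autoab"] = time.time() - t

    t = time.time()
    genes = [c for c in bundle.expression.columns if c != "batch"]
    log_expr = np.log2(bundle.expression[genes] + 1.0)
    covs = participants.set_index("sample_id")[["age", "sex"]].copy()
    covs["batch"] = bundle.expression["batch"]
    keep = participants.set_index("sample_id")["karyotype"]
    model = scores.fit_covariate_adjustment(log_expr, covs, keep=keep)
    adjusted = scores.apply_adjustment(model, log_expr, covs)
    panel = scores.select_isg_panel(bundle.de_results, genes,
                                    q_max=config["fdr"])
    z, _ = scores.reference_zscores(adjusted, controls)
    ifn = scores.composite_score(z, panel.genes, score_type="IFN",
                                 mode=config["score_mode"])
    score_table = ifn.values.rename("ifn_score").to_frame()
    score_table.index.name = "sample_id"
    write_table(score_table.reset_index(), out / "ifn_scores.tsv")
    timings["scores"] = time.time() - t

    t = time.time()
    collapsed, report = markers.preprocess_analytes(
        bundle.analytes, flag_threshold=config["flag_threshold"])
    da = markers.differential_abundance(collapsed, participants,
                                        fdr=config["fdr"])
    write_table(collapsed, out / "analytes_collapsed.tsv")
    write_table(report, out / "analyte_flags.tsv")
    write_table(da, out / "analyte_differential_abundance.tsv")
    timings["markers"] = time.time() - t

    t = time.time()
    comp = composition.run_composition_analysis(bundle.frequencies,
                                                participants,
                                                fdr=config["fdr"])
    write_table(comp, out / "composition_results.tsv")
    timings["composition"] = time.time() - t

    t = time.time()
    endpoint_rows = []
    for meas in sorted(bundle.trial["measurement"].unique()):
        for week in (2, 8, 16):
            n_dec, n_eval = trial_mod.count_decreasing(bundle.trial, meas, week)
            endpoint_rows.append((meas, week, n_dec, n_eval))
    endpoints = pd.DataFrame(
        endpoint_rows,
        columns=["measurement", "week", "n_decreased", "n_evaluable"])
    for meas, uln in config["uln"].items():
        if meas in set(bundle.trial["measurement"]):
            resp = trial_mod.uln_response(
                bundle.trial, trial_mod.ThresholdRule(meas, float(uln)))
            (out / f"uln_response_{meas}.json").write_text(
                json.dumps({k: v for k, v in resp.items()
                            if k != "decreased_by_week"}
                           | {"decreased_by_week":
                              {str(k): v for k, v in
                               resp["decreased_by_week"].items()}},
                           indent=2))
    write_table(endpoints, out / "trial_endpoints.tsv")
    timings["trial"] = time.time() - t

    manifest = {
        "seed": int(config["seed"]),
        "config_digest": config.digest,
        "params": config.params,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_participants": int(len(participants)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
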