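"""Sample-table I/O, network export and the end-to-end pipeline.

Sample CSVs use comma separators with either decimal points or decimal
commas on read (composition tables in the source literature print
``24,24``-style values) and decimal points on write.  Network exports
cover Graphviz DOT, GraphML and a flat adjacency CSV that round-trips the
edge set exactly.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .correlation import (
    VariableEncoding,
    encode_dataset,
    pearson_with_pvalues,
)
from .exceptions import ConfigurationError, InvalidInputError, ValidationError
from .network import (
    DEFAULT_TAU,
    DEFAULT_TIE_EPS,
    Network,
    PartialCorrelationNetwork,
)
from .profiles import (
    DEFAULT_CLOSURE_TOL,
    FattyAcidProfile,
    OilSample,
    derive_indices,
    validate_profile,
)
from .quality import (
    AbsorbanceRecord,
    TitrationRecord,
    quality_from_readings,
)

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("sample_id", "region", "extraction",
                     "palmitic", "stearic", "oleic", "linoleic")

_QUALITY_COLUMNS = ("V_naoh_ml", "C_naoh", "V_koh_ml", "N_koh", "mass_g",
                    "A630", "A670", "A710", "A470", "A725", "path_cm")


def parse_decimal(text: str) -> float:
    """Parse a number written with either a decimal point or a decimal comma."""
    s = str(text).strip()
    if not s:
        raise InvalidInputError("empty numeric field")
    try:
        return float(s.replace(",", "."))
    except ValueError as exc:
        raise InvalidInputError(f"unparseable numeric value {text!r}") from exc


def read_samples(
    path, tol: float = DEFAULT_CLOSURE_TOL
) -> list[OilSample]:
    """Read and validate oil samples from a CSV sample table.

    Required columns: sample_id, region, extraction and the four acid
    percentages.  Optional raw-reading columns (titration volumes,
    absorbances) populate each sample's quality indices.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"missing required column(s) {missing} in {path.name}")
        samples: list[OilSample] = []
        seen_ids: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                profile = FattyAcidProfile(
                    palmitic=parse_decimal(row["palmitic"]),
                    stearic=parse_decimal(row["stearic"]),
                    oleic=parse_decimal(row["oleic"]),
                    linoleic=parse_decimal(row["linoleic"]),
                )
                validate_profile(profile, tol=tol)
                quality = _quality_from_row(row)
            except (InvalidInputError, ValidationError) as exc:
                raise type(exc)(f"{path.name} line {lineno}: {exc}") from exc
            sid = row["sample_id"].strip()
            if sid in seen_ids:
                raise ValidationError(f"{path.name} line {lineno}: duplicate sample_id {sid!r}")
            seen_ids.add(sid)
            samples.append(
                OilSample(sid, row["region"].strip(), row["extraction"].strip(),
                          profile, quality)
            )
    if not samples:
        raise ValidationError(f"no samples found in {path.name}")
    return samples


def _quality_from_row(row: dict):
    present = {c: row[c] for c in _QUALITY_COLUMNS if row.get(c, "").strip()}
    if not present:
        return None
    acidity = index = absorbance = None
    if "V_naoh_ml" in present:
        acidity = TitrationRecord(
            V=parse_decimal(present["V_naoh_ml"]),
            C=parse_decimal(present.get("C_naoh", "0.177")),
            m=parse_decimal(present.get("mass_g", "5")),
        )
    if "V_koh_ml" in present:
        index = TitrationRecord(
            V=parse_decimal(present["V_koh_ml"]),
            N=parse_decimal(present.get("N_koh", "0.1")),
            m=parse_decimal(present.get("mass_g", "1")),
        )
    ab_cols = [c for c in ("A630", "A670", "A710", "A470", "A725") if c in present]
    if ab_cols:
        absorbance = AbsorbanceRecord(
            **{c: parse_decimal(present[c]) for c in ab_cols},
            L=parse_decimal(present.get("path_cm", "1")),
        )
    return quality_from_readings(acidity, index, absorbance)


def write_samples(samples: Sequence[OilSample], path) -> None:
    """Write samples in the same CSV dialect :func:`read_samples` accepts."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_REQUIRED_COLUMNS)
        for s in samples:
            w.writerow([
                s.sample_id, s.region, s.extraction,
                repr(float(s.profile.palmitic)), repr(float(s.profile.stearic)),
                repr(float(s.profile.oleic)), repr(float(s.profile.linoleic)),
            ])


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def export_network(net: Network, fmt: str, path) -> Path:
    """Write the network as Graphviz DOT, GraphML, or adjacency CSV."""
    path = Path(path)
    if fmt == "dot":
        path.write_text(network_to_dot(net), encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "directed", "rho", "B"])
            for u, v, rho, b in net.directed_arcs:
                w.writerow([u, v, 1, repr(rho), repr(b)])
            for u, v, rho in net.undirected_edges:
                w.writerow([u, v, 0, repr(rho), ""])
    else:
        raise ConfigurationError(f"unknown network export format {fmt!r}")
    return path


def network_to_dot(net: Network) -> str:
    """Graphviz DOT text; undirected ties are drawn without arrowheads."""
    lines = ["digraph partial_correlation_network {"]
    for node in net.nodes:
        lines.append(f'  "{node}";')
    for u, v, rho, b in net.directed_arcs:
        lines.append(f'  "{u}" -> "{v}" [label="rho={rho:.3f}, B={b:.3f}"];')
    for u, v, rho in net.undirected_edges:
        lines.append(f'  "{u}" -> "{v}" [dir=none, label="rho={rho:.3f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def read_network_csv(path) -> tuple[list[tuple[str, str, float, float]],
                                    list[tuple[str, str, float]]]:
    """Read back an adjacency CSV: (directed arcs, undirected edges)."""
    arcs, und = [], []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if int(row["directed"]):
                arcs.append((row["source"], row["target"],
                             float(row["rho"]), float(row["B"])))
            else:
                und.append((row["source"], row["target"], float(row["rho"])))
    return arcs, und


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis end to end."""

    input: str
    outdir: str = "arganet_out"
    shrinkage: Optional[float] = None  #: None = analytic (auto)
    tau: float = DEFAULT_TAU
    tie_eps: float = DEFAULT_TIE_EPS
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    closure_tol: float = DEFAULT_CLOSURE_TOL
    seed: int = 0
    region_codes: Optional[dict] = None
    extraction_codes: Optional[dict] = None

    def encoding(self) -> VariableEncoding:
        kwargs = {}
        if self.region_codes:
            kwargs["region_codes"] = self.region_codes
        if self.extraction_codes:
            kwargs["extraction_codes"] = self.extraction_codes
        return VariableEncoding(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """File paths and in-memory tables produced by one pipeline run."""

    config: PipelineConfig
    indices_table: pd.DataFrame
    quality_table: Optional[pd.DataFrame]
    correlation_tidy: pd.DataFrame
    network: Network
    paths: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Sample CSV -> derived indices, quality report, correlations, network.

    Deterministic for a fixed input, configuration and seed; every output
    directory carries a run log echoing the configuration and its hash.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage_times: dict[str, float] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            t = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            stage_times[name] = round(time.time() - t, 4)
            logger.info("stage %s done in %.3fs", name, stage_times[name])
            return out
        return wrap

    samples = stage("read")(read_samples, config.input, tol=config.closure_tol)

    # derived indices table
    rows = []
    for s in samples:
        idx = derive_indices(s.profile)
        rows.append({
            "sample_id": s.sample_id, "region": s.region, "extraction": s.extraction,
            "palmitic": s.profile.palmitic, "stearic": s.profile.stearic,
            "oleic": s.profile.oleic, "linoleic": s.profile.linoleic,
            "total_sfa": round(idx.total_sfa, 2), "total_ufa": round(idx.total_ufa, 2),
            "ps_index": round(idx.ps_index, 2), "ufa_sfa_ratio": round(idx.ufa_sfa_ratio, 2),
        })
    indices_table = pd.DataFrame(rows)
    paths["indices"] = outdir / "derived_indices.csv"
    indices_table.to_csv(paths["indices"], index=False)

    # quality table when raw readings were present
    quality_table = None
    qrows = [
        {"sample_id": s.sample_id,
         "free_acidity": s.quality.free_acidity, "acid_index": s.quality.acid_index,
         "polyphenol": s.quality.polyphenol, "chlorophyll": s.quality.chlorophyll,
         "carotenoid": s.quality.carotenoid, "grade": s.quality.grade}
        for s in samples if s.quality is not None
    ]
    if qrows:
        quality_table = pd.DataFrame(qrows)
        paths["quality"] = outdir / "quality_report.csv"
        quality_table.to_csv(paths["quality"], index=False)

    # correlation screening
    enc = config.encoding()
    X = stage("encode")(encode_dataset, samples, enc)
    corr = stage("correlate")(pearson_with_pvalues, X, config.alpha_levels)
    corr.encoding = enc
    tidy = corr.tidy().round({"r": 3, "p": 3})
    paths["correlation_tidy"] = outdir / "correlation_tidy.csv"
    tidy.to_csv(paths["correlation_tidy"], index=False)
    paths["correlation_r"] = outdir / "correlation_r.csv"
    corr.r.round(3).to_csv(paths["correlation_r"])
    paths["correlation_p"] = outdir / "correlation_p.csv"
    corr.pval.round(3).to_csv(paths["correlation_p"])

    # network
    def _fit():
        model = PartialCorrelationNetwork(X)
        return model.fit(shrinkage=config.shrinkage, tau=config.tau,
                         tie_eps=config.tie_eps)
    results = stage("network")(_fit)
    net = results.network
    for fmt in ("dot", "graphml", "csv"):
        paths[f"network_{fmt}"] = export_network(
            net, fmt, outdir / f"network.{fmt if fmt != 'csv' else 'edges.csv'}"
        )
    (outdir / "network_summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
    paths["network_summary"] = outdir / "network_summary.txt"

    # run log with config echo
    log = {
        "arganet_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_samples": len(samples),
        "shrinkage_used": results.shrinkage,
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t0, 4),
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2, default=str) + "\n",
                                encoding="utf-8")

    return ReportBundle(config=config, indices_table=indices_table,
                        quality_table=quality_table, correlation_tidy=tidy,
                        network=net, paths=paths)
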