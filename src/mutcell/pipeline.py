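"""End-to-end orchestration: abundance -> mutation matrix -> association ->
risk signature -> figures, with a machine-readable run manifest.

Each stage writes its outputs under the run directory and records a content
hash (inputs + the parameters that affect it) in ``manifest.json``; re-running
with an unchanged configuration skips stages whose hash and outputs are
intact. A failing stage leaves partial outputs plus a ``FAILED`` marker
naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import io as mio
from .errors import MutcellError, ValidationError
from .model import MutationImmuneModel
from .plots import PlotSpec

log = logging.getLogger("mutcell")


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters; defaults are the method's stated defaults."""

    out_dir: str | Path = "mutcell_run"
    expression: str | None = None
    gene_sets: str | None = None
    abundance: str | None = None
    maf: str | None = None
    mutation_matrix: str | None = None
    survival: str | None = None
    min_freq: float = 0.01
    sam_fdr: float = 0.05
    fisher_fdr: float = 0.05
    z_threshold: float = 2.0
    alpha: float = 0.25
    ssgsea_normalize: bool = True
    n_perm: int = 1000
    seed: int | None = None
    barcode_length: int | None = 15
    global_fdr: bool = False
    survival_gene: str | None = None
    plots: bool = True
    plot_format: str = "png"

    def validate(self) -> None:
        for name, lo, hi in (
            ("min_freq", 0.0, 1.0),
            ("sam_fdr", 0.0, 1.0),
            ("fisher_fdr", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be > 0")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if self.seed is None:
            raise ValidationError("seed is required (the permutation test is stochastic)")
        for path_attr in ("expression", "gene_sets", "abundance", "maf",
                          "mutation_matrix", "survival"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{path_attr} input not found: {p}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Key=value config file (one pair per line, '#' comments); CLI
        overrides win."""
        values: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown option {key!r}")
            values[key] = _coerce(val, fields[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d


def _coerce(val: str, typ: str) -> Any:
    if val.lower() in ("true", "false"):
        return val.lower() == "true"
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(parts: list[str]) -> str:
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, Any] = {"stages": {}}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                self.data = {"stages": {}}

    def stage_current(self, name: str, digest: str, outputs: list[Path]) -> bool:
        entry = self.data.get("stages", {}).get(name)
        return (
            entry is not None
            and entry.get("hash") == digest
            and all(p.exists() for p in outputs)
        )

    def record(self, name: str, digest: str, outputs: list[Path]) -> None:
        self.data.setdefault("stages", {})[name] = {
            "hash": digest,
            "outputs": [str(p) for p in outputs],
        }

    def save(self, config: RunConfig, inputs: dict[str, str]) -> None:
        self.data["config"] = config.to_dict()
        self.data["inputs_sha256"] = inputs
        self.data["version"] = __version__
        self.data["seed"] = config.seed
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> Path:
    """Execute every pipeline stage; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest = _Manifest(out / "manifest.json")

    input_hashes = {
        name: _sha256(Path(p))
        for name in ("expression", "gene_sets", "abundance", "maf",
                     "mutation_matrix", "survival")
        if (p := getattr(config, name)) is not None
    }

    stage = "setup"
    try:
        # -- stage: cells ---------------------------------------------------
        stage = "cells"
        abundance_out = out / "abundance.tsv"
        cells_hash = _stage_hash([
            input_hashes.get("expression", ""), input_hashes.get("gene_sets", ""),
            input_hashes.get("abundance", ""), str(config.alpha),
            str(config.ssgsea_normalize), str(config.barcode_length),
        ])
        from .scoring import SsgseaParams

        params = SsgseaParams(alpha=config.alpha, normalize=config.ssgsea_normalize)
        if manifest.stage_current("cells", cells_hash, [abundance_out]):
            log.info("stage cells: up to date, skipped")
            model = MutationImmuneModel.from_files(
                abundance=abundance_out,
                maf=config.maf, mutation_matrix=config.mutation_matrix,
                survival=config.survival, min_freq=config.min_freq,
                barcode_length=config.barcode_length,
            )
        else:
            model = MutationImmuneModel.from_files(
                expression=config.expression, gene_sets=config.gene_sets,
                abundance=config.abundance,
                maf=config.maf, mutation_matrix=config.mutation_matrix,
                survival=config.survival, min_freq=config.min_freq,
                barcode_length=config.barcode_length, ssgsea=params,
            )
            mio.write_matrix(model.abundance, abundance_out)
            manifest.record("cells", cells_hash, [abundance_out])
        log.info("stage cells: %d cells x %d samples", *model.abundance.shape)

        # -- stage: mutmat --------------------------------------------------
        stage = "mutmat"
        mut_out = out / "mutation_matrix.tsv"
        mio.write_matrix(model.mutations.data, mut_out)
        manifest.record("mutmat", _stage_hash([
            input_hashes.get("maf", ""), input_hashes.get("mutation_matrix", ""),
            str(config.min_freq), str(config.barcode_length)]), [mut_out])
        log.info("stage mutmat: %d genes x %d samples", *model.mutations.data.shape)

        # -- stage: associate -----------------------------------------------
        stage = "associate"
        results = model.fit(
            sam_fdr=config.sam_fdr, fisher_fdr=config.fisher_fdr,
            z_threshold=config.z_threshold, n_perm=config.n_perm,
            seed=config.seed, global_fdr=config.global_fdr,
        )
        summary = results.summary()
        summary_out = out / "summary.tsv"
        summary.to_csv(summary_out, sep="\t", index=False)
        detail_dir = out / "detail"
        detail_dir.mkdir(exist_ok=True)
        detail_outs = []
        for gene, res in results.associations.items():
            log.info("gene %s: %d driven cell(s)", gene, len(res.driven_cells))
            if res.table.empty:
                continue
            p = detail_dir / f"{gene}.tsv"
            res.table.to_csv(p, sep="\t", index=False)
            detail_outs.append(p)
        manifest.record("associate", _stage_hash([
            cells_hash, str(config.sam_fdr), str(config.fisher_fdr),
            str(config.z_threshold), str(config.n_perm), str(config.seed),
            str(config.global_fdr)]), [summary_out, *detail_outs])

        # -- stage: plots ---------------------------------------------------
        driven_genes = list(summary["gene"]) if not summary.empty else []
        if config.plots and driven_genes:
            stage = "plots"
            fmt = config.plot_format
            results.plot_waterfall(PlotSpec(out / f"waterfall.{fmt}"), driven_genes)
            if len(driven_genes) >= 2:
                results.plot_cooccurrence(PlotSpec(out / f"cooc_mutex.{fmt}"), driven_genes)
            top = driven_genes[0]
            results.plot_heatmap(top, PlotSpec(out / f"heatmap_{top}.{fmt}"))

        # -- stage: survcell ------------------------------------------------
        if config.survival is not None and driven_genes:
            stage = "survcell"
            gene = config.survival_gene or driven_genes[0]
            if gene not in driven_genes:
                raise ValidationError(f"survival_gene {gene!r} has no driven cells")
            risk = results.risk_model(gene).fit()
            risk.summary().to_csv(out / f"risk_cox_{gene}.tsv", sep="\t",
                                  index_label="cell")
            pd.DataFrame({"risk_score": risk.risk_scores, "group": risk.groups}).to_csv(
                out / f"risk_groups_{gene}.tsv", sep="\t", index_label="sample")
            (out / f"logrank_{gene}.json").write_text(json.dumps(
                {"gene": gene, "chi_square": risk.logrank_chi2,
                 "p": risk.logrank_p}, indent=2) + "\n")
            if config.plots:
                risk.plot_km(PlotSpec(out / f"km_{gene}.{config.plot_format}"))
            log.info("stage survcell: gene %s log-rank p = %.3g", gene, risk.logrank_p)

        manifest.save(config, input_hashes)
        return out
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, MutcellError):
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        raise MutcellError(f"stage {stage!r} failed: {exc}") from exc
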