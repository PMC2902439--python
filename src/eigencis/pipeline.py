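"""End-to-end orchestration and the ``eigencis`` command-line interface.

``run_all`` wires the stages together for two systems: preprocessing ->
per-system SVD -> eigenarray matching -> cis-feature tables -> BN
parent-set selection with cross-system validation (both directions, per
conserved eigensystem) -> motif-count regressions.  Every run writes a
manifest with sha256 checksums of all artifacts, the config echo and the
seed, and is deterministic given the seed.

Exit codes: 0 success, 2 configuration error, 3 data-contract error,
4 numerical failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import bncisreg, cisfeatures, countreg, eigencompare, exprprep, synthdata
from .errors import ConfigError, DataContractError, EigencisError, NumericalError

log = logging.getLogger("eigencis")


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class SystemPaths:
    signal: Path
    calls: Path
    design: Path
    probeset_map: Path


@dataclasses.dataclass
class RunConfig:
    system_a: SystemPaths
    system_b: SystemPaths
    cns: Path
    motifs: Path
    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    eigensystems: tuple[int, ...] = (2, 3)
    count_species: str = "rat"
    bde: bncisreg.BDeConfig = dataclasses.field(default_factory=bncisreg.BDeConfig)
    regression_families: tuple[str, ...] | None = None
    path_family: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            sysp = {
                key: SystemPaths(**{k: Path(v) for k, v in raw["systems"][key].items()})
                for key in ("a", "b")
            }
            bde = bncisreg.BDeConfig(**raw.get("bde", {}))
            return cls(
                system_a=sysp["a"],
                system_b=sysp["b"],
                cns=Path(raw["cns"]),
                motifs=Path(raw["motifs"]),
                outdir=Path(raw.get("outdir", "eigencis_out")),
                seed=int(raw.get("seed", 0)),
                alpha=float(raw.get("alpha", 0.05)),
                eigensystems=tuple(raw.get("eigensystems", (2, 3))),
                count_species=raw.get("count_species", "rat"),
                bde=bde,
                regression_families=(
                    tuple(raw["regression_families"]) if "regression_families" in raw else None
                ),
                path_family=raw.get("path_family"),
                log_level=raw.get("log_level", "INFO"),
            )
        except (KeyError, TypeError) as e:
            raise ConfigError(f"invalid run config {path}: {e}") from e

    def validate(self) -> None:
        self.bde.validate()
        for sp in (self.system_a, self.system_b):
            for f in dataclasses.fields(sp):
                p = getattr(sp, f.name)
                if not Path(p).exists():
                    raise ConfigError(f"input file missing: {p}")
        for p in (self.cns, self.motifs):
            if not Path(p).exists():
                raise ConfigError(f"input file missing: {p}")


def _read_tsv(path: Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def _load_system(sp: SystemPaths):
    signal = _read_tsv(sp.signal, index_col=0)
    calls = _read_tsv(sp.calls, index_col=0)
    design = _read_tsv(sp.design)
    pmap = _read_tsv(sp.probeset_map)
    return signal, calls, design, pmap


def run_all(config: RunConfig) -> dict:
    """Execute the full comparative analysis; returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(df: pd.DataFrame, name: str, index_label=None) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=index_label is not None, index_label=index_label)
        artifacts.append(p)
        return p

    stage = "preprocess"
    try:
        gems = {}
        for label, sp in (("a", config.system_a), ("b", config.system_b)):
            signal, calls, design, pmap = _load_system(sp)
            gem = exprprep.preprocess(signal, calls, design, pmap, alpha=config.alpha)
            gems[label] = gem
            save(gem.values, f"expression_{label}.tsv", index_label="gene_id")
            save(gem.pvalues.to_frame(), f"anova_p_{label}.tsv", index_label="gene_id")
            log.info("system %s: %d genes pass ANOVA at alpha=%.3g",
                     label, len(gem.values), config.alpha)

        stage = "svd"
        eig = {label: eigencompare.decompose(gem) for label, gem in gems.items()}
        for label, e in eig.items():
            eigencompare.write_decomposition(e, out, f"svd_{label}")
            artifacts += [out / f"svd_{label}_{x}.tsv"
                          for x in ("eigenarrays", "eigengenes", "singular_values")]

        stage = "match"
        matches, grid = eigencompare.match_eigenarrays(eig["a"], eig["b"])
        save(eigencompare.match_report(matches), "match_report.tsv")
        save(grid, "match_grid.tsv", index_label="eigensystem_a")
        match_of = {m.k_a: m for m in matches}

        stage = "features"
        cns_raw = _read_tsv(config.cns)
        motif_tab = _read_tsv(config.motifs)
        union_genes = sorted(set(gems["a"].genes) | set(gems["b"].genes))
        ft = cisfeatures.build_feature_table(
            cns_raw, motif_tab, genes=union_genes, count_species=config.count_species
        )
        cisfeatures.write_feature_table(ft, out, prefix="features")
        artifacts += [out / f"features_{x}.tsv" for x in ("presence", "dictionary", "counts")]

        stage = "bn"
        bn_results = {}
        for k in config.eigensystems:
            m = match_of.get(k)
            if m is None:
                raise DataContractError(f"eigensystem {k} has no cross-system match")
            signed = {
                "a": eigencompare.binarize_loadings(eig["a"], k),
                "b": eigencompare.binarize_loadings(eig["b"], m.k_b),
            }
            labels_b = signed["b"].labels * (-1 if m.sign_flip else 1)
            sels = {}
            for i, (label, y) in enumerate(
                (("a", signed["a"].labels), ("b", labels_b))
            ):
                X = ft.presence.reindex(y.index).fillna(False)
                cfg_sys = dataclasses.replace(
                    config.bde, seed=config.seed + 1000 * k + 100 * i
                )
                sels[label] = bncisreg.fit_system(X, y, cfg_sys)
                pd.Series(sels[label].null_scores_, name="null_best_score_log").to_csv(
                    out / f"bn_null_{label}_E{k}.tsv", sep="\t", index_label="permutation"
                )
                artifacts.append(out / f"bn_null_{label}_E{k}.tsv")
            for train, test in (("a", "b"), ("b", "a")):
                rep = bncisreg.cross_validate(sels[train], sels[test], config.bde)
                rep_out = rep.drop(columns=["parents"], errors="ignore")
                save(rep_out, f"bn_features_train_{train}_test_{test}_E{k}.tsv")
                for rank, row in rep.iterrows():
                    cpt = sels[train].cpt(row["parents"])
                    save(cpt, f"bn_cpt_train_{train}_E{k}_rank{rank + 1}.tsv")
                bn_results[(k, train)] = rep
            meta = {
                "eigensystem": k,
                "match": {"k_b": m.k_b, "r": m.r, "sign_flip": bool(m.sign_flip)},
                "config": dataclasses.asdict(config.bde),
                "seed": config.seed,
            }
            p = out / f"bn_meta_E{k}.json"
            p.write_text(json.dumps(meta, indent=2))
            artifacts.append(p)

        stage = "regress"
        fams = config.regression_families
        if fams is None:
            seen: list[str] = []
            for rep in bn_results.values():
                for parents in rep.get("parents", []):
                    for cid in parents:
                        seen += cid.split("_")
            fams = tuple(dict.fromkeys(seen))[:4] or tuple(ft.counts.columns[1:3])
        for k in config.eigensystems:
            m = match_of[k]
            for label, kk in (("a", k), ("b", m.k_b)):
                e = eig[label]
                loadings = e.eigenarrays.iloc[:, kk - 1]
                if label == "b" and m.sign_flip:
                    loadings = -loadings
                counts = ft.counts.reindex(loadings.index).fillna(0).astype(int)
                rows = []
                for fam in fams:
                    if fam not in counts.columns:
                        continue
                    reg = countreg.GroupedCountRegression(require_cns=True)
                    try:
                        reg.fit(
                            counts[[fam]], loadings, eligibility_counts=counts["cns_count"]
                        )
                    except (DataContractError, NumericalError) as err:
                        log.warning("regression %s/E%d/%s skipped: %s", label, k, fam, err)
                        continue
                    rows.append(
                        {
                            "family": fam,
                            "alpha": float(reg.coef_[0]),
                            "se": float(reg.stderr_[0]),
                            "p": float(reg.pvalues_[0]),
                            "r_squared": reg.rsquared_,
                            "gq_stat": reg.gq_.statistic if reg.gq_ else np.nan,
                            "gq_p": reg.gq_.pvalue if reg.gq_ else np.nan,
                            "shapiro_p": reg.normality_[1],
                            "n_groups": len(reg.groups_.table),
                        }
                    )
                    save(
                        reg.groups_.table,
                        f"reg_groups_{label}_E{k}_{fam}.tsv",
                    )
                if rows:
                    save(pd.DataFrame(rows), f"reg_fits_{label}_E{k}.tsv")
                pf = config.path_family or (fams[0] if fams else None)
                if pf and pf in counts.columns:
                    try:
                        graph = countreg.path_analysis(
                            loadings, counts["cns_count"], counts[pf]
                        )
                    except (DataContractError, NumericalError) as err:
                        log.warning("path analysis %s/E%d skipped: %s", label, k, err)
                    else:
                        p = out / f"path_{label}_E{k}_{pf}.json"
                        p.write_text(
                            json.dumps(
                                {
                                    name: {"alpha": e_["alpha"], "p": e_["p"]}
                                    for name, e_ in graph.edges.items()
                                },
                                indent=2,
                            )
                        )
                        artifacts.append(p)
    except EigencisError:
        marker = out / "FAILED"
        marker.write_text(f"stage: {stage}\n")
        log.error("pipeline failed during stage %r; partial outputs retained", stage)
        raise

    manifest = {
        "seed": config.seed,
        "alpha": config.alpha,
        "eigensystems": list(config.eigensystems),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def simulate_bundle(synth_cfg: synthdata.SynthConfig, outdir: Path) -> dict[str, Path]:
    bundle = synthdata.simulate(synth_cfg)
    return synthdata.write_bundle(bundle, outdir)


# ---------------------------------------------------------------------------
# CLI


def _run(fn, *a, **kw):
    try:
        return fn(*a, **kw)
    except ConfigError as e:
        click.echo(f"config error: {e}", err=True)
        sys.exit(2)
    except DataContractError as e:
        click.echo(f"data error: {e}", err=True)
        sys.exit(3)
    except NumericalError as e:
        click.echo(f"numerical error: {e}", err=True)
        sys.exit(4)


@click.group()
def main() -> None:
    """Comparative eigensystem analysis of cis-regulation."""


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML with a 'synth' section of SynthConfig fields.")
@click.option("--seed", type=int, default=0)
@click.option("--out", "outdir", type=click.Path(), required=True)
def simulate(config_path, seed, outdir):
    """Generate a synthetic two-system bundle (expression + cis tables)."""
    def go():
        kw = {}
        if config_path:
            raw = yaml.safe_load(Path(config_path).read_text()) or {}
            kw = raw.get("synth", raw)
        kw.setdefault("seed", seed)
        cfg = synthdata.SynthConfig.from_dict(kw)
        paths = simulate_bundle(cfg, Path(outdir))
        click.echo(f"wrote {len(paths)} files to {outdir}", err=True)
    _run(go)


@main.command()
@click.option("--signal", type=click.Path(exists=True), required=True)
@click.option("--calls", type=click.Path(exists=True), required=True)
@click.option("--design", type=click.Path(exists=True), required=True)
@click.option("--probeset-map", type=click.Path(exists=True), required=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--out", "outprefix", type=click.Path(), required=True)
def preprocess(signal, calls, design, probeset_map, alpha, outprefix):
    """Detection filter, gene averaging, log2, ANOVA filter."""
    def go():
        gem = exprprep.preprocess(
            _read_tsv(Path(signal), index_col=0),
            _read_tsv(Path(calls), index_col=0),
            _read_tsv(Path(design)),
            _read_tsv(Path(probeset_map)),
            alpha=alpha,
        )
        gem.values.to_csv(f"{outprefix}_expression.tsv", sep="\t", index_label="gene_id")
        gem.pvalues.to_csv(f"{outprefix}_anova_p.tsv", sep="\t", index_label="gene_id")
    _run(go)


@main.command()
@click.option("--expr", type=click.Path(exists=True), required=True)
@click.option("--out", "outprefix", required=True)
def svd(expr, outprefix):
    """Decompose a gene-expression matrix into eigensystems."""
    def go():
        e = eigencompare.decompose(_read_tsv(Path(expr), index_col=0))
        p = Path(outprefix)
        eigencompare.write_decomposition(e, p.parent if p.parent != Path("") else Path("."),
                                         p.name)
    _run(go)


@main.command()
@click.option("--expr-a", type=click.Path(exists=True), required=True)
@click.option("--expr-b", type=click.Path(exists=True), required=True)
@click.option("--k-max", type=int, default=None)
@click.option("--out", "outpath", type=click.Path(), required=True)
def match(expr_a, expr_b, k_max, outpath):
    """Match eigenarrays across systems on the common genes."""
    def go():
        ea = eigencompare.decompose(_read_tsv(Path(expr_a), index_col=0))
        eb = eigencompare.decompose(_read_tsv(Path(expr_b), index_col=0))
        matches, _ = eigencompare.match_eigenarrays(ea, eb, k_max=k_max)
        eigencompare.match_report(matches).to_csv(outpath, sep="\t", index=False)
    _run(go)


@main.command()
@click.option("--cns", type=click.Path(exists=True), required=True)
@click.option("--motifs", type=click.Path(exists=True), required=True)
@click.option("--count-species", default="rat", show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def features(cns, motifs, count_species, outdir):
    """Build the gene x composite-motif feature table and counts."""
    def go():
        cns_raw = _read_tsv(Path(cns))
        accepted, _ = cisfeatures.validate_cns(cns_raw)
        click.echo(json.dumps(cisfeatures.cns_summary(accepted)), err=True)
        ft = cisfeatures.build_feature_table(
            cns_raw, _read_tsv(Path(motifs)), count_species=count_species
        )
        cisfeatures.write_feature_table(ft, Path(outdir))
    _run(go)


@main.command(name="run-all")
@click.option("--config", "config_path", type=click.Path(), required=True)
def run_all_cmd(config_path):
    """Full two-system analysis from a YAML run config."""
    def go():
        if not Path(config_path).exists():
            raise ConfigError(f"config file missing: {config_path}")
        manifest = run_all(RunConfig.from_yaml(config_path))
        click.echo(json.dumps({"n_artifacts": len(manifest["artifacts"])}), err=True)
    _run(go)


if __name__ == "__main__":  # pragma: no cover
    main()
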