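"""Paired synthetic datasets with planted, recoverable regulatory structure.

The generator emulates the data regime of a two-system comparative study:
two time-series microarray experiments (5 and 10 conditions, 3 replicates
each, partially overlapping gene sets) whose replicate-averaged log2
expression matrices share a small set of dominant eigensystems, plus a
table of conserved non-coding sequences (CNSs) holding conserved
transcription-factor motif-family instances for every gene.

Planted structure, all optional and configured through :class:`SynthConfig`:

* ``k_shared`` eigensystems whose eigenarrays (gene loadings) are identical
  on the shared genes in both systems while the eigengenes (temporal
  patterns) are system specific.  Eigensystem 1 has a constant-in-time
  eigengene and an all-positive eigenarray, so it plays the role of the
  average expression magnitude.
* binary composite-motif effects on the *sign* of the loading of a chosen
  eigensystem (an odds multiplier for positive sign among carrier genes);
* linear motif-count effects on the loading itself (beta loading-units per
  conserved rat-track instance);
* an antagonist motif pair: the count effect of motif A is suppressed in
  genes that also carry blocker motif S, and blocker carriers get a
  constant negative loading offset (repression).

Every stochastic draw consumes from one ``numpy.random.Generator`` seeded
from ``SynthConfig.seed``, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

# Mnemonics for motif families (position-weight-matrix families); families
# beyond the list get generic MF### names.
_FAMILY_NAMES = [
    "AP1F", "SATB", "CREB", "EGRF", "LHXF", "AHRR", "ZF5F", "ZBPF", "PARF",
    "E4FF", "AP1R", "NFKB", "SP1F", "ETSF", "OCT1", "MYOD", "HEAT", "IRFF",
    "STAT", "GATA", "SORY", "FKHD", "NKXH", "PAX5", "RBPF", "CLOX", "BRNF",
    "HOXF", "MEF2", "CAAT",
]


def family_names(n: int) -> list[str]:
    names = list(_FAMILY_NAMES[:n])
    while len(names) < n:
        names.append(f"MF{len(names) + 1:03d}")
    return names


@dataclass(frozen=True)
class SignFeature:
    """Planted binary effect of a composite motif on loading sign.

    Carrier genes have their loading sign on ``eigensystem`` resampled with
    positive-sign odds multiplied by ``odds`` (odds=1 leaves the null 50/50).
    """

    composite: tuple[str, ...]
    odds: float
    eigensystem: int = 2
    systems: str = "both"  # "both" | "A" | "B"


@dataclass(frozen=True)
class CountEffect:
    """Planted linear effect of a motif-family count on a loading."""

    family: str
    beta: float
    eigensystem: int = 3
    systems: str = "both"
    suppressed_by: str | None = None  # blocker family nullifying the effect


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_genes_a: int = 2600
    n_genes_b: int = 2200
    frac_shared: float = 0.3
    n_conditions_a: int = 5
    n_conditions_b: int = 10
    n_replicates: int = 3
    k_shared: int = 3
    # Singular values at the default ~2000-gene scale; eigensystem 1 carries
    # the expression magnitude (baseline ~8 log2 units for a 5-condition
    # system), 2 and 3 carry responses of up to ~2 log2 units for the
    # top-loading genes.
    singular_values: tuple[float, ...] = (800.0, 60.0, 45.0)
    noise_sd: float = 0.2
    n_motif_families: int = 30
    cns_per_gene_mean: float = 2.0
    motifs_per_cns_mean: float = 3.0
    # ~2.5 instances per conserved family per CNS, the census regime of the
    # emulated human-rat alignment database
    extra_instances_mean: float = 1.5
    decoy_rate: float = 0.2
    multi_probeset_frac: float = 0.0
    planted_sign_features: tuple[SignFeature, ...] = ()
    planted_count_effect: tuple[CountEffect, ...] = ()
    antagonist_pair: tuple[str, str] | None = None
    antagonist_beta: float = 0.02
    antagonist_blocker_shift: float = 0.015
    antagonist_eigensystem: int = 2

    def validate(self) -> None:
        counts = {
            "n_genes_a": self.n_genes_a,
            "n_genes_b": self.n_genes_b,
            "n_conditions_a": self.n_conditions_a,
            "n_conditions_b": self.n_conditions_b,
            "n_replicates": self.n_replicates,
            "k_shared": self.k_shared,
            "n_motif_families": self.n_motif_families,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if not 0.0 <= self.frac_shared <= 1.0:
            raise ConfigError(f"frac_shared must lie in [0,1], got {self.frac_shared}")
        if self.n_shared < 1:
            raise ConfigError("frac_shared * min(n_genes) must be >= 1")
        if self.k_shared > min(self.n_conditions_a, self.n_conditions_b) - 1:
            raise ConfigError(
                "k_shared must leave at least one condition of headroom: "
                f"k_shared={self.k_shared}, min conditions="
                f"{min(self.n_conditions_a, self.n_conditions_b)}"
            )
        sv = np.asarray(self.singular_values, dtype=float)
        if len(sv) != self.k_shared:
            raise ConfigError("singular_values must have length k_shared")
        if not np.all(sv > 0):
            raise ConfigError("singular_values must be strictly positive")
        if np.any(np.diff(sv) > 0):
            raise ConfigError("singular_values must be descending")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        n_spec_a = self.n_genes_a - self.n_shared
        n_spec_b = self.n_genes_b - self.n_shared
        if min(self.n_shared, n_spec_a, n_spec_b) < self.k_shared:
            raise ConfigError(
                "each gene block (shared / system-specific) needs at least "
                "k_shared genes for an orthonormal loading construction"
            )
        fams = set(family_names(self.n_motif_families))
        for f in self.sign_features():
            if not 1 <= len(f.composite) <= 3:
                raise ConfigError(
                    f"planted composite motif {f.composite} has size "
                    f"{len(f.composite)}; composite motifs have 1-3 families"
                )
            unknown = set(f.composite) - fams
            if unknown:
                raise ConfigError(f"unknown motif families in planted feature: {unknown}")
            if f.odds <= 0:
                raise ConfigError("sign-feature odds multiplier must be positive")
            if not 1 <= f.eigensystem <= self.k_shared:
                raise ConfigError("sign-feature eigensystem out of range")
        for e in self.count_effects():
            if e.family not in fams:
                raise ConfigError(f"unknown motif family {e.family!r} in count effect")
            if not 1 <= e.eigensystem <= self.k_shared:
                raise ConfigError("count-effect eigensystem out of range")

    @property
    def n_shared(self) -> int:
        return int(round(self.frac_shared * min(self.n_genes_a, self.n_genes_b)))

    def count_effects(self) -> tuple[CountEffect, ...]:
        """Configured count effects, with the antagonist pair expanded.

        The antagonist pair (A, S) plants a linear count effect of A on the
        chosen eigensystem that is zeroed for genes also carrying S.
        """
        effects = tuple(self.planted_count_effect)
        if self.antagonist_pair is not None:
            a, s = self.antagonist_pair
            k = self.antagonist_eigensystem
            effects += (
                CountEffect(a, self.antagonist_beta, eigensystem=k, suppressed_by=s),
            )
        return effects

    def sign_features(self) -> tuple[SignFeature, ...]:
        return tuple(self.planted_sign_features)

    @classmethod
    def from_dict(cls, raw: dict) -> "SynthConfig":
        """Build a config from plain YAML/JSON data (lists and dicts)."""
        kw = dict(raw)
        if "singular_values" in kw:
            kw["singular_values"] = tuple(float(s) for s in kw["singular_values"])
        if "antagonist_pair" in kw and kw["antagonist_pair"] is not None:
            kw["antagonist_pair"] = tuple(kw["antagonist_pair"])
        feats = []
        for f in kw.get("planted_sign_features", ()):
            if isinstance(f, dict):
                f = SignFeature(
                    composite=tuple(f["composite"]),
                    odds=float(f["odds"]),
                    eigensystem=int(f.get("eigensystem", 2)),
                    systems=f.get("systems", "both"),
                )
            feats.append(f)
        kw["planted_sign_features"] = tuple(feats)
        effects = kw.get("planted_count_effect", ())
        if isinstance(effects, dict):
            effects = (effects,)
        parsed = []
        for e in effects:
            if isinstance(e, dict):
                e = CountEffect(
                    family=e["family"],
                    beta=float(e["beta"]),
                    eigensystem=int(e.get("eigensystem", 3)),
                    systems=e.get("systems", "both"),
                    suppressed_by=e.get("suppressed_by"),
                )
            parsed.append(e)
        kw["planted_count_effect"] = tuple(parsed)
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(f"invalid synthetic-data config: {exc}") from exc


@dataclass
class GroundTruth:
    """Planted quantities of one simulation run.

    ``eigenarrays_*`` are the base orthonormal gene-loading matrices (unit
    columns, mutually orthogonal within a system; shared genes carry
    identical rows in both systems).  ``loadings_*`` are the per-gene true
    loadings actually used for expression synthesis, i.e. the base
    eigenarrays after planted sign/count effects; they are deliberately not
    re-normalised so planted slopes stay in stated units.
    """

    genes_a: list[str]
    genes_b: list[str]
    shared_genes: list[str]
    singular_values: np.ndarray
    eigenarrays_a: pd.DataFrame
    eigenarrays_b: pd.DataFrame
    eigengenes_a: pd.DataFrame
    eigengenes_b: pd.DataFrame
    loadings_a: pd.DataFrame
    loadings_b: pd.DataFrame
    planted: dict = field(default_factory=dict)
    cns_table: pd.DataFrame | None = None
    motif_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        def df(d: pd.DataFrame) -> dict:
            return {
                "index": list(map(str, d.index)),
                "columns": list(map(str, d.columns)),
                "values": d.to_numpy().tolist(),
            }

        return {
            "genes_a": self.genes_a,
            "genes_b": self.genes_b,
            "shared_genes": self.shared_genes,
            "singular_values": np.asarray(self.singular_values).tolist(),
            "eigenarrays_a": df(self.eigenarrays_a),
            "eigenarrays_b": df(self.eigenarrays_b),
            "eigengenes_a": df(self.eigengenes_a),
            "eigengenes_b": df(self.eigengenes_b),
            "loadings_a": df(self.loadings_a),
            "loadings_b": df(self.loadings_b),
            "planted": self.planted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def undf(x: dict) -> pd.DataFrame:
            return pd.DataFrame(x["values"], index=x["index"], columns=x["columns"])

        return cls(
            genes_a=list(d["genes_a"]),
            genes_b=list(d["genes_b"]),
            shared_genes=list(d["shared_genes"]),
            singular_values=np.asarray(d["singular_values"], dtype=float),
            eigenarrays_a=undf(d["eigenarrays_a"]),
            eigenarrays_b=undf(d["eigenarrays_b"]),
            eigengenes_a=undf(d["eigengenes_a"]),
            eigengenes_b=undf(d["eigengenes_b"]),
            loadings_a=undf(d["loadings_a"]),
            loadings_b=undf(d["loadings_b"]),
            planted=dict(d["planted"]),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def equals(self, other: "GroundTruth", tol: float = 0.0) -> bool:
        if (self.genes_a, self.genes_b, self.shared_genes) != (
            other.genes_a,
            other.genes_b,
            other.shared_genes,
        ):
            return False
        if self.planted != other.planted:
            return False
        pairs = [
            (self.singular_values, other.singular_values),
            (self.eigenarrays_a.to_numpy(), other.eigenarrays_a.to_numpy()),
            (self.eigenarrays_b.to_numpy(), other.eigenarrays_b.to_numpy()),
            (self.eigengenes_a.to_numpy(), other.eigengenes_a.to_numpy()),
            (self.eigengenes_b.to_numpy(), other.eigengenes_b.to_numpy()),
            (self.loadings_a.to_numpy(), other.loadings_a.to_numpy()),
            (self.loadings_b.to_numpy(), other.loadings_b.to_numpy()),
        ]
        return all(np.allclose(x, y, rtol=0, atol=tol) for x, y in pairs)


@dataclass
class SynthBundle:
    """Everything one simulation run produces."""

    config: SynthConfig
    truth: GroundTruth
    signal_a: pd.DataFrame
    calls_a: pd.DataFrame
    design_a: pd.DataFrame
    probeset_map_a: pd.DataFrame
    signal_b: pd.DataFrame
    calls_b: pd.DataFrame
    design_b: pd.DataFrame
    probeset_map_b: pd.DataFrame
    cns_table: pd.DataFrame
    motif_table: pd.DataFrame


# ---------------------------------------------------------------------------
# construction of the planted eigensystems


def _qr_block(rng: np.random.Generator, n: int, k: int, positive_first: bool) -> np.ndarray:
    m = rng.standard_normal((n, k))
    if positive_first:
        m[:, 0] = 1.0 + 0.25 * np.abs(rng.standard_normal(n))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))  # deterministic orientation
    return q


def _base_truth(config: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    n_sh = config.n_shared
    n_a, n_b, k = config.n_genes_a, config.n_genes_b, config.k_shared
    n_spec_a, n_spec_b = n_a - n_sh, n_b - n_sh

    genes_sh = [f"G{i:05d}" for i in range(n_sh)]
    genes_spec_a = [f"G{i:05d}" for i in range(n_sh, n_sh + n_spec_a)]
    genes_spec_b = [f"G{i:05d}" for i in range(n_sh + n_spec_a, n_sh + n_spec_a + n_spec_b)]
    genes_a = genes_sh + genes_spec_a
    genes_b = genes_sh + genes_spec_b

    # Shared block with weight c, system-specific blocks with weight 1-c,
    # all orthonormal, so each system's stacked loading matrix is exactly
    # orthonormal while shared genes carry identical loadings.
    c = n_sh / (n_sh + 0.5 * (n_spec_a + n_spec_b))
    q_sh = _qr_block(rng, n_sh, k, positive_first=True)
    q_a = _qr_block(rng, n_spec_a, k, positive_first=True)
    q_b = _qr_block(rng, n_spec_b, k, positive_first=True)
    u_a = np.vstack([np.sqrt(c) * q_sh, np.sqrt(1 - c) * q_a])
    u_b = np.vstack([np.sqrt(c) * q_sh, np.sqrt(1 - c) * q_b])

    def eigengenes(n_cond: int) -> np.ndarray:
        m = np.column_stack(
            [np.ones(n_cond), rng.standard_normal((n_cond, k - 1))]
            if k > 1
            else [np.ones(n_cond)]
        )
        q, r = np.linalg.qr(m)
        return q * np.sign(np.diag(r))

    v_a = eigengenes(config.n_conditions_a)
    v_b = eigengenes(config.n_conditions_b)

    cond_a = [f"ca{j + 1}" for j in range(config.n_conditions_a)]
    cond_b = [f"cb{j + 1}" for j in range(config.n_conditions_b)]
    ks = [f"E{j + 1}" for j in range(k)]

    return GroundTruth(
        genes_a=genes_a,
        genes_b=genes_b,
        shared_genes=genes_sh,
        singular_values=np.asarray(config.singular_values, dtype=float),
        eigenarrays_a=pd.DataFrame(u_a, index=genes_a, columns=ks),
        eigenarrays_b=pd.DataFrame(u_b, index=genes_b, columns=ks),
        eigengenes_a=pd.DataFrame(v_a, index=cond_a, columns=ks),
        eigengenes_b=pd.DataFrame(v_b, index=cond_b, columns=ks),
        loadings_a=pd.DataFrame(u_a.copy(), index=genes_a, columns=ks),
        loadings_b=pd.DataFrame(u_b.copy(), index=genes_b, columns=ks),
        planted={},
    )


# ---------------------------------------------------------------------------
# CNS and motif-instance tables


def _gen_cis(
    config: SynthConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = truth.genes_a + [g for g in truth.genes_b if g not in set(truth.genes_a)]
    fams = np.array(family_names(config.n_motif_families))
    cns_rows: list[tuple] = []
    motif_rows: list[tuple] = []

    n_cns_per_gene = rng.poisson(config.cns_per_gene_mean, size=len(genes))
    for gene, n_cns in zip(genes, n_cns_per_gene):
        for i in range(int(n_cns)):
            cns_id = f"CNS_{gene}_{i + 1}"
            length = int(100 + rng.exponential(90.0))
            identity = float(np.round(rng.uniform(0.75, 0.97), 4))
            for species in ("human", "rat"):
                chrom = f"chr{int(rng.integers(1, 21))}"
                start = int(rng.integers(1_000, 5_000_000))
                cns_rows.append(
                    (cns_id, gene, species, chrom, start, start + length, identity)
                )
            m = min(1 + int(rng.poisson(max(config.motifs_per_cns_mean - 1.0, 0.0))), len(fams))
            chosen = rng.choice(len(fams), size=m, replace=False)
            n_inst = 0
            for fi in chosen:
                fam = str(fams[fi])
                for species in ("human", "rat"):
                    k_inst = 1 + int(rng.poisson(config.extra_instances_mean))
                    for _ in range(k_inst):
                        pos = int(rng.integers(0, max(length - 10, 1)))
                        strand = "+" if rng.random() < 0.5 else "-"
                        motif_rows.append((cns_id, species, fam, pos, strand))
                        n_inst += 1
            # decoy non-conserved instances: single-species, families absent
            # from this CNS, at a configurable fraction of instances
            n_dec = int(rng.poisson(config.decoy_rate * n_inst)) if config.decoy_rate > 0 else 0
            if n_dec:
                chosen_set = set(chosen.tolist())
                others = [i for i in range(len(fams)) if i not in chosen_set]
                for _ in range(n_dec if others else 0):
                    fam = str(fams[others[int(rng.integers(0, len(others)))]])
                    species = "human" if rng.random() < 0.5 else "rat"
                    pos = int(rng.integers(0, max(length - 10, 1)))
                    strand = "+" if rng.random() < 0.5 else "-"
                    motif_rows.append((cns_id, species, fam, pos, strand))

    cns = pd.DataFrame(
        cns_rows,
        columns=["cns_id", "gene_id", "species", "chrom", "start", "end", "pct_identity"],
    )
    motifs = pd.DataFrame(
        motif_rows, columns=["cns_id", "species", "family_id", "start", "strand"]
    )
    return cns, motifs


# ---------------------------------------------------------------------------
# planted effects


def _carriers(composite: tuple[str, ...], cns_families: pd.DataFrame) -> set[str]:
    """Genes with some CNS conserving every family of the composite."""
    want = set(composite)
    by_cns = cns_families.groupby("cns_id")["family_id"].agg(set)
    gene_of = cns_families.drop_duplicates("cns_id").set_index("cns_id")["gene_id"]
    out: set[str] = set()
    for cns_id, fams in by_cns.items():
        if want <= fams:
            out.add(gene_of[cns_id])
    return out


def _plant_effects(config: SynthConfig, truth: GroundTruth, rng: np.random.Generator) -> None:
    from . import cisfeatures

    if not config.sign_features() and not config.count_effects():
        return
    cns_valid, rejected = cisfeatures.validate_cns(truth.cns_table)
    conserved = cisfeatures.conserved_motifs(
        cns_valid, truth.motif_table, rejected_ids=set(rejected["cns_id"])
    )
    all_genes = sorted(set(truth.genes_a) | set(truth.genes_b))
    counts = cisfeatures.count_features(
        cns_valid, conserved, truth.motif_table, genes=all_genes
    )

    planted: dict = {"sign_features": [], "count_effects": []}

    for feat in config.sign_features():
        carriers = _carriers(feat.composite, conserved)
        p_pos = feat.odds / (1.0 + feat.odds)
        draw = {g: (1.0 if rng.random() < p_pos else -1.0) for g in sorted(carriers)}
        col = truth.loadings_a.columns[feat.eigensystem - 1]
        for sysname, ldf in (("A", truth.loadings_a), ("B", truth.loadings_b)):
            if feat.systems not in ("both", sysname):
                continue
            for g, s in draw.items():
                if g in ldf.index:
                    ldf.loc[g, col] = abs(ldf.loc[g, col]) * s
        planted["sign_features"].append(
            {
                "composite": list(feat.composite),
                "odds": feat.odds,
                "eigensystem": feat.eigensystem,
                "systems": feat.systems,
                "n_carriers": len(carriers),
            }
        )

    for eff in config.count_effects():
        fam_counts = (
            counts[eff.family] if eff.family in counts.columns else pd.Series(0, index=all_genes)
        )
        if eff.suppressed_by is not None:
            blockers = _carriers((eff.suppressed_by,), conserved)
        else:
            blockers = set()
        col = truth.loadings_a.columns[eff.eigensystem - 1]
        for sysname, ldf in (("A", truth.loadings_a), ("B", truth.loadings_b)):
            if eff.systems not in ("both", sysname):
                continue
            add = fam_counts.reindex(ldf.index).fillna(0).astype(float) * eff.beta
            add[add.index.isin(blockers)] = 0.0
            ldf[col] = ldf[col] + add
        planted["count_effects"].append(
            {
                "family": eff.family,
                "beta": eff.beta,
                "eigensystem": eff.eigensystem,
                "systems": eff.systems,
                "suppressed_by": eff.suppressed_by,
            }
        )

    # the blocker side of an antagonist pair: a count-independent negative
    # loading offset for blocker carriers (repression), which gives the
    # blocker its marginal association with down-regulation without tying
    # the shift to any motif count
    if config.antagonist_pair is not None:
        _, blocker = config.antagonist_pair
        carriers = _carriers((blocker,), conserved)
        col = truth.loadings_a.columns[config.antagonist_eigensystem - 1]
        for ldf in (truth.loadings_a, truth.loadings_b):
            hit = [g for g in ldf.index if g in carriers]
            ldf.loc[hit, col] = ldf.loc[hit, col] - config.antagonist_blocker_shift
        planted["blocker_shift"] = {
            "family": blocker,
            "shift": config.antagonist_blocker_shift,
            "eigensystem": config.antagonist_eigensystem,
            "n_carriers": len(carriers),
        }

    truth.planted = planted


# ---------------------------------------------------------------------------
# expression synthesis


def _design(system: str, conditions: list[str], n_rep: int) -> pd.DataFrame:
    times = {
        "A": [0.0, 6.0, 12.0, 24.0, 48.0],
        "B": [1.0, 6.0, 24.0, 72.0, 240.0, 1.0, 6.0, 24.0, 72.0, 240.0],
    }.get(system, list(range(len(conditions))))
    rows = []
    for j, cond in enumerate(conditions):
        t = times[j] if j < len(times) else float(j)
        if system == "A":
            treatment = "control" if j == 0 else "treated"
        else:
            treatment = "treated" if j < len(conditions) // 2 else "control"
        for r in range(1, n_rep + 1):
            rows.append((f"{system}_{cond}_r{r}", cond, t, treatment, r))
    return pd.DataFrame(
        rows, columns=["array_id", "condition_id", "time_h", "treatment", "replicate"]
    )


def _gen_expression_system(
    config: SynthConfig,
    loadings: pd.DataFrame,
    eigengenes: pd.DataFrame,
    sv: np.ndarray,
    design: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    genes = list(loadings.index)
    conds = list(eigengenes.index)
    x_mean = loadings.to_numpy() @ np.diag(sv) @ eigengenes.to_numpy().T
    cond_pos = {c: j for j, c in enumerate(conds)}
    cols = [cond_pos[c] for c in design["condition_id"]]
    log2_rep = x_mean[:, cols] + rng.normal(0.0, config.noise_sd, size=(len(genes), len(cols)))

    probesets = [f"PS_{g}_1" for g in genes]
    signal = pd.DataFrame(
        np.power(2.0, log2_rep), index=probesets, columns=list(design["array_id"])
    )
    mapping = pd.DataFrame({"probeset_id": probesets, "gene_id": genes})
    if config.multi_probeset_frac > 0:
        extra = [g for g in genes if rng.random() < config.multi_probeset_frac]
        if extra:
            idx = [genes.index(g) for g in extra]
            jitter = rng.normal(0.0, 0.05, size=(len(extra), len(cols)))
            sig2 = np.power(2.0, log2_rep[idx, :] + jitter)
            ps2 = [f"PS_{g}_2" for g in extra]
            signal = pd.concat(
                [signal, pd.DataFrame(sig2, index=ps2, columns=signal.columns)]
            )
            mapping = pd.concat(
                [mapping, pd.DataFrame({"probeset_id": ps2, "gene_id": extra})],
                ignore_index=True,
            )
    calls = pd.DataFrame("P", index=signal.index, columns=signal.columns)
    return signal, calls, mapping


# ---------------------------------------------------------------------------
# public API


def simulate(config: SynthConfig) -> SynthBundle:
    """Run the full generator: expression, design, cis tables, ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _base_truth(config, rng)
    cns, motifs = _gen_cis(config, truth, rng)
    truth.cns_table, truth.motif_table = cns, motifs
    _plant_effects(config, truth, rng)

    design_a = _design("A", list(truth.eigengenes_a.index), config.n_replicates)
    design_b = _design("B", list(truth.eigengenes_b.index), config.n_replicates)
    sig_a, calls_a, map_a = _gen_expression_system(
        config, truth.loadings_a, truth.eigengenes_a, truth.singular_values, design_a, rng
    )
    sig_b, calls_b, map_b = _gen_expression_system(
        config, truth.loadings_b, truth.eigengenes_b, truth.singular_values, design_b, rng
    )
    return SynthBundle(
        config=config,
        truth=truth,
        signal_a=sig_a,
        calls_a=calls_a,
        design_a=design_a,
        probeset_map_a=map_a,
        signal_b=sig_b,
        calls_b=calls_b,
        design_b=design_b,
        probeset_map_b=map_b,
        cns_table=cns,
        motif_table=motifs,
    )


def generate_paired_expression(config: SynthConfig):
    """Paired replicate-level expression matrices plus designs and truth."""
    b = simulate(config)
    return (
        (b.signal_a, b.calls_a, b.probeset_map_a),
        (b.signal_b, b.calls_b, b.probeset_map_b),
        b.design_a,
        b.design_b,
        b.truth,
    )


def generate_cis_tables(config: SynthConfig, truth: GroundTruth):
    """CNS and motif-instance tables attached to a generated ground truth."""
    if truth.cns_table is None or truth.motif_table is None:
        raise ConfigError("truth carries no cis tables; run simulate() first")
    return truth.cns_table, truth.motif_table, truth


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all bundle tables as TSV (+ truth JSON); returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def w(name: str, df: pd.DataFrame, index_label: str | None = None) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index_label is not None, index_label=index_label)
        paths[name] = p

    for sysname in ("a", "b"):
        w(f"signal_{sysname}.tsv", getattr(bundle, f"signal_{sysname}"), "probeset_id")
        w(f"calls_{sysname}.tsv", getattr(bundle, f"calls_{sysname}"), "probeset_id")
        w(f"design_{sysname}.tsv", getattr(bundle, f"design_{sysname}"))
        w(f"probeset_map_{sysname}.tsv", getattr(bundle, f"probeset_map_{sysname}"))
    w("cns.tsv", bundle.cns_table)
    w("motifs.tsv", bundle.motif_table)
    truth_path = out / "truth.json"
    bundle.truth.save_json(truth_path)
    paths["truth.json"] = truth_path
    return paths
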