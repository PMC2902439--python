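"""Data model for conserved non-coding sequences and their motif content.

A CNS (conserved non-coding sequence) is a >=100 bp window of a two-species
alignment with >=75% identity, treated as a putative regulatory region of
its gene.  A motif family is *conserved* in a CNS when both species' tracks
carry at least one instance (aligned position irrelevant).  A composite
motif is a set of 1-3 families all conserved within one CNS; a gene carries
a composite if any of its CNSs does.  Motif counts per gene are conserved
instance counts on a designated count species (default rat), summed over
the gene's valid CNSs.

Coordinates follow BED conventions (0-based, half-open).  Matrix-to-family
collapsing is assumed done upstream: instance rows carry ``family_id``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataContractError

CNS_COLUMNS = ["cns_id", "gene_id", "species", "chrom", "start", "end", "pct_identity"]
MOTIF_COLUMNS = ["cns_id", "species", "family_id", "start", "strand"]

MIN_CNS_LENGTH = 100
MIN_CNS_IDENTITY = 0.75


def composite_id(families) -> str:
    """Canonical composite id: families sorted, joined by underscores."""
    return "_".join(sorted(families))


@dataclass
class GeneFeatureTable:
    """Gene-level binary composite-motif presence plus per-gene counts."""

    presence: pd.DataFrame  # genes x composite ids, bool
    composites: dict[str, tuple[str, ...]]  # composite id -> family tuple
    counts: pd.DataFrame  # genes x (cns_count + per-family instance counts)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    def restrict_genes(self, genes) -> "GeneFeatureTable":
        genes = [g for g in genes if g in self.presence.index]
        return GeneFeatureTable(
            presence=self.presence.loc[genes],
            composites=self.composites,
            counts=self.counts.loc[genes],
        )


def validate_cns(
    table: pd.DataFrame,
    min_length: int = MIN_CNS_LENGTH,
    min_identity: float = MIN_CNS_IDENTITY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply CNS validity rules; returns (accepted, rejected-with-reason).

    A CNS is valid when it has a row for both species and every row passes
    the inclusive length and identity thresholds with end > start.
    """
    missing = [c for c in CNS_COLUMNS if c not in table.columns]
    if missing:
        raise DataContractError(f"CNS table lacks columns: {missing}")
    t = table.copy()
    length = t["end"] - t["start"]
    reasons = pd.Series("", index=t.index, dtype=object)
    reasons[~(t["end"] > t["start"])] = "end<=start"
    short = (length < min_length) & (reasons == "")
    reasons[short] = f"length<{min_length}"
    weak = (t["pct_identity"] < min_identity) & (reasons == "")
    reasons[weak] = f"identity<{min_identity}"
    row_ok = reasons == ""
    n_species = t[row_ok].groupby("cns_id")["species"].nunique()
    paired = set(n_species[n_species >= 2].index)
    unpaired = row_ok & ~t["cns_id"].isin(paired)
    reasons[unpaired] = "missing species track"
    accepted = t[reasons == ""]
    rejected = t[reasons != ""].assign(reason=reasons[reasons != ""])
    return accepted, rejected


def cns_summary(accepted: pd.DataFrame) -> dict:
    """Descriptive statistics of accepted CNSs (count, mean/SD length)."""
    lengths = (accepted["end"] - accepted["start"]).astype(float)
    return {
        "n_cns": int(accepted["cns_id"].nunique()),
        "n_genes": int(accepted["gene_id"].nunique()),
        "mean_length_bp": float(lengths.mean()) if len(lengths) else float("nan"),
        "sd_length_bp": float(lengths.std()) if len(lengths) > 1 else float("nan"),
    }


def conserved_motifs(
    cns: pd.DataFrame, instances: pd.DataFrame, rejected_ids=()
) -> pd.DataFrame:
    """(cns_id, gene_id, family_id) pairs with instances on both species tracks.

    Instance rows must reference cns_ids present in ``cns`` or explicitly
    listed in ``rejected_ids`` (ids dropped by :func:`validate_cns`); any
    other id raises.
    """
    missing = [c for c in MOTIF_COLUMNS if c not in instances.columns]
    if missing:
        raise DataContractError(f"motif table lacks columns: {missing}")
    known = set(cns["cns_id"])
    unknown = sorted(set(instances["cns_id"]) - known - set(rejected_ids))
    if unknown:
        raise DataContractError(f"motif instances reference unknown cns_ids: {unknown[:10]}")
    inst = instances[instances["cns_id"].isin(known)]
    per = inst.groupby(["cns_id", "family_id"])["species"].nunique()
    both = per[per >= 2].reset_index()[["cns_id", "family_id"]]
    gene_of = cns.drop_duplicates("cns_id").set_index("cns_id")["gene_id"]
    both["gene_id"] = both["cns_id"].map(gene_of)
    return both[["cns_id", "gene_id", "family_id"]]


def check_instances_known(cns_raw: pd.DataFrame, instances: pd.DataFrame) -> None:
    """Raise when instance rows reference cns_ids absent from the raw table."""
    unknown = sorted(set(instances["cns_id"]) - set(cns_raw["cns_id"]))
    if unknown:
        raise DataContractError(f"motif instances reference unknown cns_ids: {unknown[:5]}")


def enumerate_composites(
    conserved: pd.DataFrame,
    max_size: int = 3,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Per-gene binary presence of all size <= max_size composites.

    Per CNS with m distinct conserved families, every non-empty subset of
    size <= max_size defines a composite present in that CNS; gene-level
    presence is the union over the gene's CNSs (so two families that never
    share a CNS do not form a gene-level pair).
    """
    if max_size not in (1, 2, 3):
        raise ConfigError("max_size must be 1, 2 or 3")
    comp_genes: dict[str, set[str]] = {}
    comp_fams: dict[str, tuple[str, ...]] = {}
    for (cns_id, gene), fams in conserved.groupby(["cns_id", "gene_id"])["family_id"]:
        fam_sorted = sorted(set(fams))
        for size in range(1, min(max_size, len(fam_sorted)) + 1):
            for combo in itertools.combinations(fam_sorted, size):
                cid = "_".join(combo)
                comp_fams.setdefault(cid, combo)
                comp_genes.setdefault(cid, set()).add(gene)
    gene_index = genes if genes is not None else sorted(
        {g for s in comp_genes.values() for g in s}
    )
    cols = sorted(comp_fams)
    gene_pos = {g: i for i, g in enumerate(gene_index)}
    arr = np.zeros((len(gene_index), len(cols)), dtype=bool)
    for j, cid in enumerate(cols):
        rows = [gene_pos[g] for g in comp_genes[cid] if g in gene_pos]
        arr[rows, j] = True
    presence = pd.DataFrame(
        arr, index=pd.Index(gene_index, name="gene_id"), columns=cols
    )
    return presence, comp_fams


def count_features(
    cns: pd.DataFrame,
    conserved: pd.DataFrame,
    instances: pd.DataFrame,
    genes: list[str] | None = None,
    count_species: str = "rat",
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene CNS count and conserved-instance counts on the count species.

    Genes with zero valid CNSs remain addressable with all-zero counts.
    """
    gene_of = cns.drop_duplicates("cns_id").set_index("cns_id")["gene_id"]
    cns_count = gene_of.groupby(gene_of).count()

    key = conserved.set_index(["cns_id", "family_id"]).index
    inst = instances[instances["species"] == count_species]
    inst = inst[inst.set_index(["cns_id", "family_id"]).index.isin(key)]
    inst = inst.assign(gene_id=inst["cns_id"].map(gene_of))
    fam_counts = (
        inst.groupby(["gene_id", "family_id"]).size().unstack(fill_value=0)
        if len(inst)
        else pd.DataFrame()
    )
    if genes is None:
        genes = sorted(set(gene_of) | set(fam_counts.index))
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["cns_count"] = cns_count.reindex(genes).fillna(0).astype(int)
    fam_list = families if families is not None else sorted(fam_counts.columns)
    for f in fam_list:
        col = (
            fam_counts[f].reindex(genes).fillna(0).astype(int)
            if f in fam_counts.columns
            else pd.Series(0, index=genes)
        )
        out[f] = col
    return out


def build_feature_table(
    cns_raw: pd.DataFrame,
    instances: pd.DataFrame,
    genes: list[str] | None = None,
    max_size: int = 3,
    count_species: str = "rat",
    min_length: int = MIN_CNS_LENGTH,
    min_identity: float = MIN_CNS_IDENTITY,
) -> GeneFeatureTable:
    """Validation -> conservation -> composites -> counts, in one call."""
    check_instances_known(cns_raw, instances)
    accepted, rejected = validate_cns(cns_raw, min_length=min_length, min_identity=min_identity)
    conserved = conserved_motifs(accepted, instances, rejected_ids=set(rejected["cns_id"]))
    presence, comp_fams = enumerate_composites(conserved, max_size=max_size, genes=genes)
    counts = count_features(
        accepted, conserved, instances, genes=list(presence.index), count_species=count_species
    )
    return GeneFeatureTable(presence=presence, composites=comp_fams, counts=counts)


def write_feature_table(ft: GeneFeatureTable, outdir, prefix: str = "features") -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    triplets = ft.presence.stack()
    triplets = triplets[triplets]
    pd.DataFrame(
        {
            "gene_id": triplets.index.get_level_values(0),
            "composite_id": triplets.index.get_level_values(1),
            "present": 1,
        }
    ).to_csv(out / f"{prefix}_presence.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(cid, len(f), "|".join(f)) for cid, f in sorted(ft.composites.items())],
        columns=["composite_id", "size", "families"],
    ).to_csv(out / f"{prefix}_dictionary.tsv", sep="\t", index=False)
    ft.counts.to_csv(out / f"{prefix}_counts.tsv", sep="\t", index_label="gene_id")
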