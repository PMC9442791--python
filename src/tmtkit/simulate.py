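"""Synthetic multi-plex TMT experiments with planted ground truth.

Generates peptide-level quantification tables (one per plex, each carrying
an internal reference channel pooled from all samples), kinase-driven
phosphosite tables, and drug-screen viability tables, together with the
planted parameters needed to verify recovery downstream.

All abundances are emitted on the linear reporter-intensity scale; effects,
offsets and noise are specified in log2 units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

QUANT_META_COLUMNS = [
    "peptide_id",
    "peptide_sequence",
    "species",
    "master_proteins",
    "id_score",
    "plex_id",
    "phospho_positions",
    "localization_ambiguous",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of a synthetic two-plex-style TMT experiment.

    Counts refer to the human (tumor) proteome; mouse/shared peptides are
    added on top so emitted species fractions match ``frac_mouse`` /
    ``frac_shared``.
    """

    n_plexes: int = 2
    channels_per_plex: int = 11
    n_samples: int = 20
    groups: Sequence[str] | None = None
    n_proteins: int = 500
    peptides_per_protein: tuple[int, int] = (1, 4)
    n_phosphosites: int = 200
    n_kinases: int = 20
    sites_per_kinase: int = 10
    group_effect_size: float = 1.0
    frac_de: float = 0.1
    plex_effect_sd: float = 0.0
    noise_sd: float = 0.0
    reference_noise_sd: float = 0.0
    frac_mouse: float = 0.0
    frac_shared: float = 0.0
    missing_rate: float = 0.0
    drug_effect: float = 0.0
    n_drug_proteins: int = 20
    duplicate_entries: int = 1
    entry_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_mouse", "frac_shared", "missing_rate", "drug_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.frac_mouse + self.frac_shared >= 1.0:
            raise ConfigurationError("frac_mouse + frac_shared must be < 1")
        if self.n_samples > self.n_plexes * (self.channels_per_plex - 1):
            raise ConfigurationError(
                f"{self.n_samples} samples do not fit in {self.n_plexes} plexes "
                f"of {self.channels_per_plex - 1} sample channels"
            )
        if self.groups is None:
            labels = ["G1", "G2", "G3"]
            self.groups = [labels[i % 3] for i in range(self.n_samples)]
        self.groups = list(self.groups)
        if len(self.groups) != self.n_samples:
            raise ConfigurationError("groups must provide one label per sample")
        if len(set(self.groups)) < 2:
            raise ConfigurationError("need at least 2 distinct groups")
        if self.n_phosphosites < self.n_kinases:
            raise ConfigurationError("need n_phosphosites >= n_kinases")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "peptides_per_protein" in d:
            d["peptides_per_protein"] = tuple(d["peptides_per_protein"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted parameters of a simulated experiment."""

    true_protein_means: pd.DataFrame  # protein x sample, log2
    true_kinase_activity: pd.DataFrame  # kinase x sample, within [0, 24]
    kinase_site_map: dict[str, tuple[str, ...]]  # site key -> kinases
    site_accessions: dict[str, tuple[str, str, int]]  # site key -> (acc, res, pos)
    drug_viability: pd.Series  # per sample, percent
    drug_associated_proteins: tuple[str, ...]
    de_proteins: dict[str, str]  # protein -> upregulated group
    plex_offsets: dict[str, float]  # per plex, log2
    sample_plex: pd.Series  # sample -> plex id
    sample_group: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        missing = set(self.drug_associated_proteins) - set(self.true_protein_means.index)
        if missing:
            raise ValueError(f"drug-associated proteins not simulated: {sorted(missing)}")
        act = self.true_kinase_activity.to_numpy()
        if act.size and (act.min() < 0 or act.max() > 24):
            raise ValueError("kinase activities must lie within [0, 24]")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent stream per logical component, split from the master seed."""
    names = ["layout", "quant", "missing", "drug", "kinase", "scores"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _random_peptide(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 16))
    return "".join(rng.choice(list(_AMINO_ACIDS), size=n)) + "K"


def generate_experiment(config: SimConfig) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Simulate a global-proteome experiment.

    Returns one peptide-level quantification table per plex (each containing
    all peptides, that plex's sample channels and its reference channel) and
    the planted ground truth. The reference channel is the noise-free linear
    mean of all samples' abundances, shifted by the plex offset — an in
    silico pool of equal peptide amounts from every sample.
    """
    rngs = _rng_streams(config.seed)
    rng = rngs["quant"]
    layout_rng = rngs["layout"]

    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    groups = pd.Series(list(config.groups), index=sample_ids, name="group")

    # random plex assignment, contiguous chunks of the shuffled order
    per_plex = config.channels_per_plex - 1
    order = layout_rng.permutation(sample_ids)
    plex_ids = [f"plex{i + 1}" for i in range(config.n_plexes)]
    sample_plex = pd.Series(index=sample_ids, dtype=object, name="plex_id")
    for i, pid in enumerate(plex_ids):
        for s in order[i * per_plex : (i + 1) * per_plex]:
            sample_plex[s] = pid
    sample_plex = sample_plex.dropna()

    plex_offsets = {
        pid: float(layout_rng.normal(0.0, config.plex_effect_sd)) if config.plex_effect_sd > 0 else 0.0
        for pid in plex_ids
    }

    proteins = [f"HP{i:05d}" for i in range(config.n_proteins)]
    baseline = rng.uniform(14.0, 22.0, size=config.n_proteins)

    # group effects on a planted subset of proteins
    n_de = int(round(config.frac_de * config.n_proteins))
    group_labels = sorted(set(groups))
    de_idx = rng.choice(config.n_proteins, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_proteins: dict[str, str] = {}
    group_shift = np.zeros((config.n_proteins, config.n_samples))
    for j, pi in enumerate(de_idx):
        g = group_labels[j % len(group_labels)]
        de_proteins[proteins[pi]] = g
        group_shift[pi, :] = np.where(groups.to_numpy() == g, config.group_effect_size, 0.0)

    # latent drug response planted into protein means
    drug_rng = rngs["drug"]
    z_v = drug_rng.standard_normal(config.n_samples)
    viability = pd.Series(
        np.clip(50.0 + 15.0 * z_v, 0.0, 100.0), index=sample_ids, name="viability"
    )
    drug_shift = np.zeros((config.n_proteins, config.n_samples))
    drug_proteins: tuple[str, ...] = ()
    if config.drug_effect > 0 and config.n_drug_proteins > 0:
        non_de = np.setdiff1d(np.arange(config.n_proteins), de_idx)
        pick = drug_rng.choice(non_de, size=min(config.n_drug_proteins, len(non_de)), replace=False)
        drug_proteins = tuple(proteins[i] for i in sorted(pick))
        # Pearson level chosen so the population Spearman matches drug_effect
        c = 2.0 * np.sin(np.pi * config.drug_effect / 6.0)
        z = (z_v - z_v.mean()) / z_v.std()
        for pi in pick:
            eps = drug_rng.standard_normal(config.n_samples)
            drug_shift[pi, :] = -c * z + np.sqrt(max(0.0, 1.0 - c * c)) * eps

    # per-peptide ionization offsets; noise-free log2 peptide means per sample
    lo, hi = config.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=config.n_proteins)
    pep_rows = []  # (peptide_id, sequence, protein_index)
    pep_offsets = []
    k = 0
    for pi, np_i in enumerate(n_peps):
        for _ in range(int(np_i)):
            pep_rows.append((f"pep{k:06d}", _random_peptide(rng), pi))
            pep_offsets.append(rng.normal(0.0, 1.0))
            k += 1
    n_human = len(pep_rows)
    pep_offsets = np.asarray(pep_offsets)
    prot_idx = np.asarray([r[2] for r in pep_rows])

    # noise-free per-sample log2 values for human peptides
    sample_log2 = (
        baseline[prot_idx][:, None]
        + pep_offsets[:, None]
        + group_shift[prot_idx, :]
        + drug_shift[prot_idx, :]
    )
    linear = np.power(2.0, sample_log2)

    # ground-truth protein means: log2 of the summed peptide intensities
    prot_linear = np.zeros((config.n_proteins, config.n_samples))
    np.add.at(prot_linear, prot_idx, linear)
    true_protein_means = pd.DataFrame(
        np.log2(prot_linear), index=proteins, columns=sample_ids
    )

    # contaminant peptides so emitted species fractions match the config
    frac_h = 1.0 - config.frac_mouse - config.frac_shared
    n_mouse = int(round(n_human * config.frac_mouse / frac_h))
    n_shared = int(round(n_human * config.frac_shared / frac_h))
    extra_rows = []
    extra_log2 = []
    for i in range(n_mouse):
        extra_rows.append((f"mpep{i:05d}", _random_peptide(rng), f"MUP{i:05d}", "mouse"))
        extra_log2.append(rng.uniform(14.0, 22.0))
    for i in range(n_shared):
        extra_rows.append((f"spep{i:05d}", _random_peptide(rng), f"SHP{i:05d}", "shared"))
        extra_log2.append(rng.uniform(14.0, 22.0))
    extra_log2 = np.asarray(extra_log2)

    miss_rng = rngs["missing"]
    tables = []
    for pid in plex_ids:
        cols = [s for s in sample_ids if sample_plex[s] == pid]
        scale = 2.0 ** plex_offsets[pid]

        human_vals = linear[:, [sample_ids.index(s) for s in cols]] * scale
        human_ref = linear.mean(axis=1) * scale
        if config.reference_noise_sd > 0:
            human_ref = human_ref * 2.0 ** rng.normal(0.0, config.reference_noise_sd, size=n_human)
        if config.noise_sd > 0:
            human_vals = human_vals * 2.0 ** rng.normal(0.0, config.noise_sd, size=human_vals.shape)

        if extra_rows:
            ev = np.power(2.0, extra_log2)[:, None] * np.ones((1, len(cols))) * scale
            if config.noise_sd > 0:
                ev = ev * 2.0 ** rng.normal(0.0, config.noise_sd, size=ev.shape)
            eref = np.power(2.0, extra_log2) * scale
            all_vals = np.vstack([human_vals, ev])
            all_ref = np.concatenate([human_ref, eref])
        else:
            all_vals, all_ref = human_vals, human_ref

        if config.missing_rate > 0:
            drop = miss_rng.random(all_vals.shape) < config.missing_rate
            all_vals = np.where(drop, np.nan, all_vals)

        meta = pd.DataFrame(
            {
                "peptide_id": [r[0] for r in pep_rows] + [r[0] for r in extra_rows],
                "peptide_sequence": [r[1] for r in pep_rows] + [r[1] for r in extra_rows],
                "species": ["human"] * n_human + [r[3] for r in extra_rows],
                "master_proteins": [proteins[i] for i in prot_idx] + [r[2] for r in extra_rows],
                "id_score": rng.uniform(150.0, 400.0, size=n_human + len(extra_rows)).round(1),
                "plex_id": pid,
                "phospho_positions": "",
                "localization_ambiguous": False,
            }
        )
        quant = pd.DataFrame(all_vals, columns=cols)
        quant[f"ref_{pid}"] = all_ref
        tables.append(pd.concat([meta, quant], axis=1))

    # kinase-substrate truth (consumed by generate_kinase_sites)
    kin_rng = rngs["kinase"]
    kinases = [f"KIN{i:03d}" for i in range(config.n_kinases)]
    activity = pd.DataFrame(
        kin_rng.uniform(4.0, 20.0, size=(config.n_kinases, config.n_samples)),
        index=kinases,
        columns=sample_ids,
    )
    residues = np.array(["S", "T", "Y"])
    site_map: dict[str, tuple[str, ...]] = {}
    site_accessions: dict[str, tuple[str, str, int]] = {}
    for i in range(config.n_phosphosites):
        acc = f"PSUB{i:05d}"
        res = str(kin_rng.choice(residues, p=[0.88, 0.115, 0.005]))
        pos = int(kin_rng.integers(1, 800))
        key = f"{acc}_{res}{pos}"
        if i < config.n_kinases:  # one private site per kinase: identifiable network
            ks: tuple[str, ...] = (kinases[i],)
        else:
            k1 = str(kin_rng.choice(kinases))
            if kin_rng.random() < 0.2:
                k2 = str(kin_rng.choice([k for k in kinases if k != k1]))
                ks = (k1, k2)
            else:
                ks = (k1,)
        site_map[key] = ks
        site_accessions[key] = (acc, res, pos)

    truth = GroundTruth(
        true_protein_means=true_protein_means,
        true_kinase_activity=activity,
        kinase_site_map=site_map,
        site_accessions=site_accessions,
        drug_viability=viability,
        drug_associated_proteins=drug_proteins,
        de_proteins=de_proteins,
        plex_offsets=plex_offsets,
        sample_plex=sample_plex,
        sample_group=groups,
    )
    return tables, truth


def generate_kinase_sites(config: SimConfig, truth: GroundTruth) -> list[pd.DataFrame]:
    """Simulate phosphopeptide tables whose site abundances are kinase-driven.

    Each phosphosite's noise-free log2 abundance in a sample is the mean of
    its assigned kinases' activities; Gaussian log2 noise and plex offsets
    are applied on top. Returns one table per plex.
    """
    if truth.true_kinase_activity.empty:
        raise ValueError("kinase activities not populated in ground truth")
    for key, ks in truth.kinase_site_map.items():
        if len(ks) == 0:
            raise ValueError(f"site {key} has no assigned kinase")

    rngs = _rng_streams(config.seed)
    rng = rngs["scores"]
    miss_rng = rngs["missing"]
    sample_ids = list(truth.true_kinase_activity.columns)
    act = truth.true_kinase_activity

    keys = list(truth.kinase_site_map)
    sequences = [_random_peptide(rng) for _ in keys]  # fixed across plexes
    site_log2 = np.vstack(
        [act.loc[list(truth.kinase_site_map[k])].mean(axis=0).to_numpy() for k in keys]
    )
    linear = np.power(2.0, site_log2)

    tables = []
    for pid in dict.fromkeys(truth.sample_plex):
        cols = [s for s in sample_ids if truth.sample_plex[s] == pid]
        scale = 2.0 ** truth.plex_offsets[pid]
        vals = linear[:, [sample_ids.index(s) for s in cols]] * scale
        ref = linear.mean(axis=1) * scale
        if config.reference_noise_sd > 0:
            ref = ref * 2.0 ** rng.normal(0.0, config.reference_noise_sd, size=len(keys))
        if config.noise_sd > 0:
            vals = vals * 2.0 ** rng.normal(0.0, config.noise_sd, size=vals.shape)
        if config.missing_rate > 0:
            drop = miss_rng.random(vals.shape) < config.missing_rate
            vals = np.where(drop, np.nan, vals)

        meta = pd.DataFrame(
            {
                "peptide_id": [f"ppep{i:05d}" for i in range(len(keys))],
                "peptide_sequence": sequences,
                "species": "human",
                "master_proteins": [truth.site_accessions[k][0] for k in keys],
                "id_score": rng.uniform(210.0, 400.0, size=len(keys)).round(1),
                "plex_id": pid,
                "phospho_positions": [
                    f"{truth.site_accessions[k][1]}{truth.site_accessions[k][2]}" for k in keys
                ],
                "localization_ambiguous": False,
            }
        )
        quant = pd.DataFrame(vals, columns=cols)
        quant[f"ref_{pid}"] = ref
        tables.append(pd.concat([meta, quant], axis=1))
    return tables


def generate_drug_table(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Emit a drug-screen viability table with duplicate screen entries.

    Columns: ``drug_id``, ``entry_id`` then one column per sample holding
    percent viability in [0, 100].
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[-1])
    rows = []
    for e in range(max(1, config.duplicate_entries)):
        v = truth.drug_viability.to_numpy().copy()
        if config.entry_noise_sd > 0:
            v = v + rng.normal(0.0, config.entry_noise_sd, size=v.shape)
        rows.append(["DRUG1", f"DRUG1_e{e + 1}", *np.clip(v, 0.0, 100.0)])
    return pd.DataFrame(
        rows, columns=["drug_id", "entry_id", *truth.drug_viability.index]
    )


# -- serialization ------------------------------------------------------

def write_quant_tables(tables: Sequence[pd.DataFrame], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tables:
        pid = t["plex_id"].iloc[0]
        p = out_dir / f"quant_{pid}.tsv"
        t.to_csv(p, sep="\t", index=False, na_rep="NA")
        paths.append(p)
    return paths


def read_quant_table(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a quantification TSV, renaming dialect columns via ``column_map``."""
    t = pd.read_csv(path, sep="\t", na_values=["NA"])
    if column_map:
        t = t.rename(columns=dict(column_map))
    missing = [c for c in QUANT_META_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"quant table lacks columns: {missing}")
    t["phospho_positions"] = t["phospho_positions"].fillna("")
    t["localization_ambiguous"] = t["localization_ambiguous"].astype(bool)
    return t


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_protein_means": truth.true_protein_means.to_dict(orient="index"),
        "true_kinase_activity": truth.true_kinase_activity.to_dict(orient="index"),
        "kinase_site_map": {k: list(v) for k, v in truth.kinase_site_map.items()},
        "site_accessions": {k: list(v) for k, v in truth.site_accessions.items()},
        "drug_viability": truth.drug_viability.to_dict(),
        "drug_associated_proteins": list(truth.drug_associated_proteins),
        "de_proteins": truth.de_proteins,
        "plex_offsets": truth.plex_offsets,
        "sample_plex": truth.sample_plex.to_dict(),
        "sample_group": truth.sample_group.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        true_protein_means=pd.DataFrame.from_dict(d["true_protein_means"], orient="index"),
        true_kinase_activity=pd.DataFrame.from_dict(d["true_kinase_activity"], orient="index"),
        kinase_site_map={k: tuple(v) for k, v in d["kinase_site_map"].items()},
        site_accessions={k: (v[0], v[1], int(v[2])) for k, v in d["site_accessions"].items()},
        drug_viability=pd.Series(d["drug_viability"]),
        drug_associated_proteins=tuple(d["drug_associated_proteins"]),
        de_proteins=d["de_proteins"],
        plex_offsets=d["plex_offsets"],
        sample_plex=pd.Series(d["sample_plex"]),
        sample_group=pd.Series(d["sample_group"]),
    )


def write_truth_gene_sets(truth: GroundTruth, path: str | Path) -> None:
    """Write planted signatures (drug-associated and per-group DE sets) as GMT."""
    lines = []
    if truth.drug_associated_proteins:
        members = "\t".join(truth.drug_associated_proteins)
        lines.append(f"PLANTED_DRUG_ASSOCIATED\tsimulated\t{members}")
    by_group: dict[str, list[str]] = {}
    for prot, g in truth.de_proteins.items():
        by_group.setdefault(g, []).append(prot)
    for g in sorted(by_group):
        members = "\t".join(sorted(by_group[g]))
        lines.append(f"PLANTED_DE_{g}\tsimulated\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")
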