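"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is seed-deterministic and returns its ground truth
alongside the data, so each pipeline stage can be tested end-to-end
without any external download:

* :func:`gen_rate_data` — a forward model of the coupled pyruvate-kinase /
  lactate-dehydrogenase ATPase assay: state occupancies from the binding
  equilibrium, composite Michaelis-Menten rates over an ATP grid, and
  multiplicative Gaussian noise.
* :func:`gen_progress_curves` — the raw A340 readout of that assay (one
  NADH oxidised per ATP regenerated through the PK/LDH couple).
* :func:`gen_alignments` — a toy genome with gene models and
  strand-specific ribosome footprints (23-41 nt, discrete-triangular
  lengths peaked at 30 nt) written as SAM + GFF3.
* :func:`gen_contrast_tables` / :func:`gen_protein_table` — ground-truth
  labelled inputs for the regulon classifier and the proteomic filter.
"""

from __future__ import annotations
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .enzymology import RateDataset, composite_rate
from .models import make_model
from .network import equilibrium_concentrations
from .riboseq import GeneModel
from .states import KineticStateSet

__all__ = [
    "AssayGeneratorConfig",
    "ReadGeneratorConfig",
    "DEFAULT_CONDITIONS",
    "gen_rate_data",
    "gen_progress_curves",
    "gen_alignments",
    "gen_contrast_tables",
    "gen_protein_table",
    "default_gene_models",
]

#: the four headline ligand conditions of the ATPase panel (uM totals):
#: basal, saturating single additions, and the combined condition
PANEL_CONDITIONS: Mapping[str, Mapping[str, float]] = {
    "basal": {"RimK": 1.0, "RimA": 0.0, "cdG": 0.0},
    "rima": {"RimK": 1.0, "RimA": 1.0, "cdG": 0.0},
    "cdg": {"RimK": 1.0, "RimA": 0.0, "cdG": 25.0},
    "rima_cdg": {"RimK": 1.0, "RimA": 1.0, "cdG": 25.0},
}

#: full default assay panel: the headline conditions plus ligand titration
#: series (activation is dose dependent around equimolar ratios, so the
#: titrations are what make the dissociation constants identifiable)
DEFAULT_CONDITIONS: Mapping[str, Mapping[str, float]] = {
    **PANEL_CONDITIONS,
    **{
        f"cdg_{c:g}": {"RimK": 1.0, "RimA": 0.0, "cdG": float(c)}
        for c in (0.25, 0.5, 1.0, 2.5, 10.0)
    },
    **{
        f"rima_{a:g}": {"RimK": 1.0, "RimA": float(a), "cdG": 0.0}
        for a in (0.1, 0.25, 0.5, 2.0)
    },
}

#: molar extinction coefficient of NADH at 340 nm, M^-1 cm^-1
NADH_EXTINCTION = 6220.0


@dataclass(frozen=True)
class AssayGeneratorConfig:
    """Ground truth and assay settings for the rate-data generator.

    Default truth is a four-state model with independent binding sites,
    Kd(cdG) = 1 uM, Kd(RimA) = 0.2 uM, additive state activities and a
    shared Km of 500 uM ATP.  ``noise`` is the Gaussian standard deviation
    as a fraction of signal.
    """

    variant: str = "four_state"
    kd: Mapping[str, float] = field(
        default_factory=lambda: {"cdg": 1.0, "rima": 0.2}
    )
    kcat: Mapping[str, float] = field(
        default_factory=lambda: {
            "apo": 20.0,
            "cdg": 60.0,
            "rima": 70.0,
            "cdg_rima": 110.0,
        }
    )
    km: Mapping[str, float] | float = 500.0
    atp_grid: tuple[float, ...] = (50.0, 100.0, 250.0, 500.0, 1000.0, 2500.0, 5000.0)
    conditions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )
    noise: float = 0.02
    nadh_extinction: float = NADH_EXTINCTION
    nadh0_mM: float = 0.4
    path_length_cm: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not self.atp_grid:
            raise ValueError("ATP grid must be nonempty")


def _truth_states(
    cfg: AssayGeneratorConfig, condition: Mapping[str, float]
) -> KineticStateSet:
    net, roster = make_model(
        cfg.variant, concentrations=condition, kd=dict(cfg.kd)
    )
    conc = equilibrium_concentrations(net)
    return roster.with_params(cfg.kcat, cfg.km).with_weights(conc)


def gen_rate_data(
    cfg: AssayGeneratorConfig, seed: Optional[int] = None
) -> tuple[list[RateDataset], dict]:
    """Noisy per-condition rate datasets plus the generating truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    s = np.asarray(cfg.atp_grid, float)
    datasets = []
    truth_rates = {}
    for label, condition in cfg.conditions.items():
        states = _truth_states(cfg, condition)
        v_true = composite_rate(states, s)
        v = v_true * (1.0 + cfg.noise * rng.standard_normal(s.size))
        datasets.append(
            RateDataset(condition=label, s=tuple(s), v=tuple(np.clip(v, 0.0, None)))
        )
        truth_rates[label] = v_true
    truth = {
        "variant": cfg.variant,
        "kd": dict(cfg.kd),
        "kcat": dict(cfg.kcat),
        "km": cfg.km,
        "rates": truth_rates,
    }
    return datasets, truth


def gen_progress_curves(
    cfg: AssayGeneratorConfig,
    atp_uM: float = 500.0,
    duration_min: float = 30.0,
    dt_min: float = 1.0,
    enzyme_scale: float = 1.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """A340 time series of the NADH-coupled assay, one column per condition.

    The PK/LDH couple oxidises one NADH per ATP regenerated, so absorbance
    declines linearly at a slope proportional to the ATPase rate until the
    NADH is exhausted; the curve never goes negative.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    a0 = cfg.nadh_extinction * cfg.path_length_cm * cfg.nadh0_mM * 1e-3
    nadh0_uM = cfg.nadh0_mM * 1e3
    data = {"time_min": t}
    for label, condition in cfg.conditions.items():
        states = _truth_states(cfg, condition)
        rate = enzyme_scale * composite_rate(states, atp_uM)  # uM NADH/min
        nadh = np.clip(nadh0_uM - rate * t, 0.0, None)
        a340 = a0 * nadh / nadh0_uM
        if cfg.noise > 0:
            a340 = np.clip(
                a340 + cfg.noise * a0 * rng.standard_normal(t.size), 0.0, None
            )
        data[label] = a340
    return pd.DataFrame(data)


# -- ribosome footprints -------------------------------------------------


def default_gene_models(
    n_genes: int = 20,
    genome_length: int = 30_000,
    reference: str = "toy1",
    gene_length: int = 900,
    rng: Optional[np.random.Generator] = None,
) -> list[GeneModel]:
    """Evenly spaced non-overlapping genes with alternating strands."""
    spacing = genome_length // n_genes
    if gene_length >= spacing:
        raise ValueError("genes would overlap; reduce gene_length or n_genes")
    genes = []
    for i in range(n_genes):
        start = i * spacing + (spacing - gene_length) // 2 + 1  # 1-based
        genes.append(
            GeneModel(
                gene_id=f"gene{i:03d}",
                reference=reference,
                strand="+" if i % 2 == 0 else "-",
                start=start,
                end=start + gene_length - 1,
            )
        )
    return genes


@dataclass(frozen=True)
class ReadGeneratorConfig:
    """Toy-genome footprint generator settings.

    Footprint lengths follow a discrete triangular distribution peaked at
    30 nt over 23..41; ``contaminant_fraction`` of reads get out-of-window
    lengths and uniform genomic positions, emulating unfiltered debris.
    """

    genome_length: int = 30_000
    reference: str = "toy1"
    n_genes: int = 20
    rates: Optional[tuple[float, ...]] = None
    depth: int = 100_000
    contaminant_fraction: float = 0.02
    length_peak: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if self.rates is not None:
            if len(self.rates) != self.n_genes:
                raise ValueError("rates length must equal n_genes")
            if any(r < 0 for r in self.rates):
                raise ValueError("rates must be >= 0")


def _triangular_length_pmf(peak: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(23, 42)
    w = np.interp(lengths, [22.0, float(peak), 42.0], [0.0, 1.0, 0.0])
    return lengths, w / w.sum()


def gen_alignments(
    cfg: ReadGeneratorConfig, out_dir: str | Path
) -> dict:
    """Write a SAM + GFF3 pair for a toy genome; return paths and truth.

    In-window reads land on their gene's strand, uniformly within the
    gene, with genes drawn multinomially proportional to rate x length.
    ``depth = 0`` produces a header-only SAM.
    """
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = default_gene_models(
        cfg.n_genes, cfg.genome_length, reference=cfg.reference
    )
    if cfg.rates is None:
        rates = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    else:
        rates = np.asarray(cfg.rates, float)

    gff_path = out_dir / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {cfg.reference} 1 {cfg.genome_length}\n")
        for g in genes:
            fh.write(
                f"{g.reference}\trimsys\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )

    lengths, length_pmf = _triangular_length_pmf(cfg.length_peak)
    contaminant_lengths = np.array([18, 19, 20, 21, 22, 42, 45, 50])
    n_contam = rng.binomial(cfg.depth, cfg.contaminant_fraction)
    n_signal = cfg.depth - n_contam
    weights = rates * np.array([g.length_nt for g in genes])
    probs = (
        weights / weights.sum()
        if weights.sum() > 0
        else np.full(len(genes), 1.0 / len(genes))
    )
    genome = rng.choice(list("ACGT"), size=cfg.genome_length)

    sam_path = out_dir / "footprints.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cfg.reference, "LN": cfg.genome_length}],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as fh:
        gene_idx = rng.choice(len(genes), size=n_signal, p=probs)
        spans = rng.choice(lengths, size=n_signal, p=length_pmf)
        records = []
        for i in range(n_signal):
            g = genes[int(gene_idx[i])]
            span = int(spans[i])
            lo, hi = g.interval0
            start = int(rng.integers(lo, hi - span + 1))
            records.append((f"read{i}", start, span, g.strand))
        for j in range(n_contam):
            span = int(rng.choice(contaminant_lengths))
            start = int(rng.integers(0, cfg.genome_length - span))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((f"contam{j}", start, span, strand))
        for name, start, span, strand in records:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = name
            rec.reference_id = 0
            rec.reference_start = start
            rec.mapping_quality = 42
            rec.cigartuples = [(0, span)]
            rec.flag = 16 if strand == "-" else 0
            rec.query_sequence = "".join(genome[start : start + span])
            fh.write(rec)

    return {
        "sam": sam_path,
        "gff3": gff_path,
        "genes": genes,
        "rates": np.asarray(rates, float),
        "n_signal": n_signal,
        "n_contaminant": n_contam,
    }


# -- contrast / proteomics tables ----------------------------------------


def gen_contrast_tables(
    proportions: Mapping[str, float],
    n_genes: int = 500,
    tau: float = 1.0,
    margin: float = 0.2,
    effect_scale: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-contrast log2 tables with known regulon labels.

    Significant effects are drawn uniformly from
    ``[tau + margin, tau + margin + effect_scale]`` (random sign subject to
    the class), non-significant ones from ``[0, tau - margin]``, so with
    ``margin > 0`` every gene is strictly beyond or inside the threshold
    and the classifier must recover the truth exactly.
    """
    labels = list(proportions)
    p = np.asarray([proportions[k] for k in labels], float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if not 0 <= margin < tau:
        raise ValueError("margin must satisfy 0 <= margin < tau")
    rng = np.random.default_rng(seed)
    truth = rng.choice(labels, size=n_genes, p=p)

    def sig(n):
        return rng.uniform(tau + margin, tau + margin + effect_scale, n) * (
            rng.integers(0, 2, n) * 2 - 1
        )

    def nonsig(n):
        return rng.uniform(0.0, max(tau - margin, 0.0), n) * (
            rng.integers(0, 2, n) * 2 - 1
        )

    a = np.zeros(n_genes)
    b = np.zeros(n_genes)
    for label in labels:
        idx = np.flatnonzero(truth == label)
        n = idx.size
        if label == "class1":
            a[idx] = sig(n)
            b[idx] = nonsig(n)
        elif label == "class2":
            a[idx] = sig(n)
            b[idx] = np.abs(sig(n)) * np.sign(a[idx])
        elif label == "class3":
            a[idx] = sig(n)
            b[idx] = -np.abs(sig(n)) * np.sign(a[idx])
        elif label == "glutamation_only":
            a[idx] = nonsig(n)
            b[idx] = sig(n)
        elif label == "unaffected":
            a[idx] = nonsig(n)
            b[idx] = nonsig(n)
        else:
            raise ValueError(f"unknown class label {label!r}")
    table = pd.DataFrame(
        {"log2_a": a, "log2_b": b},
        index=[f"gene{i:04d}" for i in range(n_genes)],
    )
    return table, pd.Series(truth, index=table.index, name="truth")


def gen_protein_table(
    n_records: int = 200,
    flagged_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """iTRAQ-style abundance-ratio records with known differential flags.

    Flagged records satisfy all three filter conditions strictly
    (>= 2 peptides, >= 2-fold regulation difference, one p <= 0.05);
    unflagged records violate exactly one, chosen at random.
    """
    rng = np.random.default_rng(seed)
    n_flagged = int(round(n_records * flagged_fraction))
    rows = []
    truth = []
    for i in range(n_records):
        flagged = i < n_flagged
        log2_wt = rng.normal(0.0, 0.4)
        if flagged:
            delta = rng.uniform(1.1, 3.0) * (1 if rng.random() < 0.5 else -1)
            peptides = int(rng.integers(2, 8))
            p_wt, p_mut = rng.uniform(0.001, 0.049), rng.uniform(0.001, 0.8)
        else:
            mode = rng.integers(0, 3)
            delta = rng.uniform(1.1, 3.0) * (1 if rng.random() < 0.5 else -1)
            peptides = int(rng.integers(2, 8))
            p_wt, p_mut = rng.uniform(0.001, 0.049), rng.uniform(0.06, 0.9)
            if mode == 0:
                peptides = 1
            elif mode == 1:
                delta = rng.uniform(-0.9, 0.9)
            else:
                p_wt, p_mut = rng.uniform(0.06, 0.9), rng.uniform(0.06, 0.9)
        rows.append(
            {
                "protein_id": f"prot{i:04d}",
                "peptides": peptides,
                "log2_wt": log2_wt,
                "log2_mut": log2_wt + delta,
                "p_wt": p_wt,
                "p_mut": p_mut,
            }
        )
        truth.append(flagged)
    table = pd.DataFrame(rows).set_index("protein_id")
    return table, pd.Series(truth, index=table.index, name="truth")
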