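"""Synthetic phosphoproteomics data with known ground truth.

Emulates a TMT-style time-resolved phosphoproteomics experiment
(WEE1-inhibitor design: 0/20/40/60/90 min, 3 biological replicates,
optionally a second 0/90 min x 4 replicate dataset): generated protein
sequences with segmental disorder tracks, kinase consensus motifs planted
at phospho-acceptor sites, and abundance time courses in which activated
substrates follow Michaelis-Menten kinetics on the log2 scale while
decoy sites stay flat or decrease linearly.

Every quantity the downstream pipeline estimates (loading biases,
replicate batch factors, kinetic parameters, motif composition, kinase
annotations) is planted explicitly and returned as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (AMINO_ACIDS, AbundanceMatrix, ProteinRecord,
                         SyntheticTruth, extract_flank)

# Approximate human proteome amino-acid frequencies (UniProt-like).
HUMAN_AA_FREQS = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}

KINETIC_CLASSES = ("fast", "slow", "decreasing", "flat")


@dataclass
class DisorderModel:
    """Two-state (ordered/disordered) segmental disorder generator.

    Segment lengths are geometric; ordered segments draw scores from
    ``ordered_range``, disordered from ``disordered_range``, so the
    conventional > 0.4 disorder filter selects roughly
    ``disordered_fraction`` of residues in a structured (run-wise) way.
    """

    disordered_fraction: float = 0.4
    mean_ordered_segment: float = 30.0
    ordered_range: tuple = (0.0, 0.45)
    disordered_range: tuple = (0.35, 1.0)

    @property
    def mean_disordered_segment(self) -> float:
        f = self.disordered_fraction
        return self.mean_ordered_segment * f / (1.0 - f)


def _aa_sampler(rng: np.random.Generator):
    letters = np.array(list(HUMAN_AA_FREQS))
    probs = np.array(list(HUMAN_AA_FREQS.values()))
    probs = probs / probs.sum()
    return lambda n: "".join(rng.choice(letters, size=n, p=probs))


def generate_proteome(n_proteins: int,
                      length_range: tuple = (300, 800),
                      disorder_model: DisorderModel | None = None,
                      seed: int = 0) -> list[ProteinRecord]:
    """Generate random protein sequences with segmental disorder tracks.

    Deterministic for a fixed seed. Lengths are drawn uniformly from
    ``length_range`` (inclusive); each protein must be long enough to
    host a full +/-10 flank plus margins.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 43:
        raise ValueError(f"invalid length range {length_range}; "
                         "minimum length is 43")
    dm = disorder_model or DisorderModel()
    rng = np.random.default_rng(seed)
    draw_seq = _aa_sampler(rng)
    records = []
    for k in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = draw_seq(length)
        disorder = np.empty(length)
        pos = 0
        # start state drawn from the stationary distribution
        state = rng.random() < dm.disordered_fraction
        while pos < length:
            mean_len = (dm.mean_disordered_segment if state
                        else dm.mean_ordered_segment)
            seg = 1 + rng.geometric(1.0 / mean_len)
            seg = min(seg, length - pos)
            a, b = dm.disordered_range if state else dm.ordered_range
            disorder[pos:pos + seg] = rng.uniform(a, b, size=seg)
            pos += seg
            state = not state
        records.append(ProteinRecord(f"SYN{k:04d}", seq, disorder))
    return records


@dataclass
class MotifSpec:
    """Positional residue preferences of a kinase consensus.

    ``prefs`` maps flank offsets (-10..+10, excluding 0) to residue ->
    probability-of-writing maps; leftover probability mass leaves the
    background residue untouched. ``center`` lists allowed
    phospho-acceptor residues.
    """

    prefs: dict = field(default_factory=dict)
    center: str = "ST"

    def __post_init__(self) -> None:
        if not set(self.center) <= set("STY") or not self.center:
            raise ValueError("center residues must be among S, T, Y")
        for off, weights in self.prefs.items():
            if not -10 <= off <= 10 or off == 0:
                raise ValueError(f"motif offset {off} outside -10..+10")
            if any(r not in AMINO_ACIDS for r in weights):
                raise ValueError(f"unknown residue in motif at {off}")
            total = sum(weights.values())
            if total > 1.0 + 1e-12 or any(w < 0 for w in weights.values()):
                raise ValueError(f"motif weights at {off} must be "
                                 "nonnegative and sum to <= 1")


#: proline-directed CDK-like consensus S/T-P-x-K/R
CDK_MOTIF = MotifSpec(prefs={1: {"P": 0.95}, 3: {"K": 0.55, "R": 0.2}})
#: basophilic control consensus R-R-x-S/T
BASOPHILIC_MOTIF = MotifSpec(prefs={-3: {"R": 0.9}, -2: {"R": 0.6}})


def plant_kinase_sites(proteome: list[ProteinRecord],
                       motif_specs: dict[str, MotifSpec],
                       n_sites_per_kinase: int | dict,
                       seed: int = 0,
                       curation_effort: int = 3,
                       ) -> tuple[pd.DataFrame, list[ProteinRecord]]:
    """Plant kinase-substrate sites matching consensus motifs.

    Rewrites flanking residues of randomly chosen acceptor positions
    according to each kinase's :class:`MotifSpec` and returns a
    kinase-substrate annotation table (kinase, accession, position,
    residue, curation_effort) together with the edited proteome.
    Placements that cannot accommodate the motif (or collide with an
    already-planted site) are re-drawn; exhausted kinases raise a
    warning rather than silently truncating flanks.
    """
    rng = np.random.default_rng(seed)
    seqs = {p.accession: list(p.sequence) for p in proteome}
    accs = [p.accession for p in proteome]
    used: set[tuple[str, int]] = set()
    rows = []
    for kinase, spec in motif_specs.items():
        n_wanted = (n_sites_per_kinase[kinase]
                    if isinstance(n_sites_per_kinase, dict)
                    else n_sites_per_kinase)
        planted = 0
        attempts = 0
        max_attempts = 200 * max(n_wanted, 1)
        while planted < n_wanted and attempts < max_attempts:
            attempts += 1
            acc = accs[rng.integers(len(accs))]
            seq = seqs[acc]
            # full-flank placement: all motif offsets must be in-sequence
            max_off = max([abs(o) for o in spec.prefs], default=0)
            margin = max(max_off, 1)
            if len(seq) < 2 * margin + 1:
                continue
            pos = int(rng.integers(margin + 1, len(seq) - margin + 1))
            if (acc, pos) in used or any(
                    (acc, pos + o) in used for o in spec.prefs):
                continue
            residue = spec.center[rng.integers(len(spec.center))]
            seq[pos - 1] = residue
            for off, weights in spec.prefs.items():
                u = rng.random()
                acc_p = 0.0
                for r, w in weights.items():
                    acc_p += w
                    if u < acc_p:
                        seq[pos - 1 + off] = r
                        break
            used.add((acc, pos))
            rows.append((kinase, acc, pos, residue, curation_effort))
            planted += 1
        if planted < n_wanted:
            warnings.warn(
                f"{kinase}: planted only {planted}/{n_wanted} sites "
                "(no valid placements left)")
    annotations = pd.DataFrame(
        rows, columns=["kinase", "accession", "position", "residue",
                       "curation_effort"])
    edited = [ProteinRecord(p.accession, "".join(seqs[p.accession]),
                            p.disorder.copy()) for p in proteome]
    return annotations, edited


def sample_decoy_sites(proteome: list[ProteinRecord], n_sites: int,
                       exclude: set | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Sample unannotated S/T acceptor positions as decoy phosphosites."""
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    pool = []
    for p in proteome:
        for i, ch in enumerate(p.sequence, start=1):
            if ch in "ST" and (p.accession, i) not in exclude:
                pool.append((p.accession, i, ch))
    if n_sites > len(pool):
        raise ValueError(f"requested {n_sites} decoys but only "
                         f"{len(pool)} S/T positions available")
    idx = rng.choice(len(pool), size=n_sites, replace=False)
    rows = [pool[i] for i in sorted(idx)]
    return pd.DataFrame(rows, columns=["accession", "position", "residue"])


def make_design(time_points=(0, 20, 40, 60, 90), n_replicates: int = 3,
                dataset: str = "tc") -> pd.DataFrame:
    """Sample design table: one sample per (time point, replicate)."""
    rows = []
    for rep in range(1, n_replicates + 1):
        for t in time_points:
            rows.append((f"{dataset}_r{rep}_t{t}", t, rep, dataset))
    df = pd.DataFrame(rows, columns=["sample_id", "time_min", "replicate",
                                     "dataset"])
    return df.set_index("sample_id")


def _noise_free_log2_signal(kinetic_class: str, t: np.ndarray, vm: float,
                            k: float, rate: float) -> np.ndarray:
    if kinetic_class in ("fast", "slow"):
        return vm * t / (k + t)
    if kinetic_class == "decreasing":
        return -rate * t
    if kinetic_class == "flat":
        return np.zeros_like(t, dtype=float)
    raise ValueError(f"unknown kinetic class {kinetic_class!r}")


@dataclass
class KineticParams:
    """Distributions of planted kinetic parameters (log2-scale signal)."""

    vm_mean: float = 2.0          # log2 plateau (~4-fold activation)
    vm_sd: float = 0.3
    k_fast: float = 10.0          # half-time, minutes
    k_slow: float = 60.0
    k_cv: float = 0.2             # lognormal CV of K around its class value
    decrease_drop_range: tuple = (0.5, 1.5)  # total log2 drop at 90 min


def generate_timecourse(sites: pd.DataFrame,
                        design: pd.DataFrame,
                        noise_sd: float = 0.1,
                        seed: int = 0,
                        loading_sd: float = 0.2,
                        replicate_offset_sd: float = 0.15,
                        baseline_log2_mean: float = 20.0,
                        baseline_log2_sd: float = 1.5,
                        kinetics: KineticParams | None = None,
                        protein_drift_fraction: float = 0.05,
                        protein_drift_log2: float = 0.5,
                        ) -> tuple[AbundanceMatrix, AbundanceMatrix,
                                   SyntheticTruth]:
    """Simulate phospho and protein abundance matrices for a design.

    ``sites`` needs columns accession, position, residue, kinetic_class
    and optionally flank, true_Vm, true_K (drawn from ``kinetics`` when
    absent). The noise-free log2 signal of a fast/slow site at time t is
    ``Vm * t / (K + t)``; decreasing sites fall linearly; flat sites are
    constant. Every abundance is then multiplied by a per-sample loading
    factor, a per-(site, replicate) batch offset and log-normal noise.
    The matched protein matrix is flat per protein (a small fraction
    drifts linearly) with its own loading factors and noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if 0 not in set(design["time_min"]):
        raise ValueError("design must include time 0 (baseline)")
    unknown = set(sites["kinetic_class"]) - set(KINETIC_CLASSES)
    if unknown:
        raise ValueError(f"unknown kinetic classes: {sorted(unknown)}")
    kp = kinetics or KineticParams()
    rng = np.random.default_rng(seed)

    sites = sites.copy()
    if "site_id" not in sites.columns:
        sites["site_id"] = [f"{a}_{r}{p}" for a, p, r in
                            zip(sites["accession"], sites["position"],
                                sites["residue"])]
    sites = sites.set_index("site_id")
    n = len(sites)

    vm = rng.normal(kp.vm_mean, kp.vm_sd, size=n).clip(min=0.5)
    k_class = sites["kinetic_class"].map(
        {"fast": kp.k_fast, "slow": kp.k_slow}).to_numpy(dtype=float)
    kk = np.where(np.isnan(k_class), np.nan,
                  k_class * np.exp(rng.normal(0.0, kp.k_cv, size=n)))
    drop = rng.uniform(*kp.decrease_drop_range, size=n)
    if "true_Vm" not in sites.columns:
        sites["true_Vm"] = np.where(
            sites["kinetic_class"].isin(["fast", "slow"]), vm, 0.0)
    if "true_K" not in sites.columns:
        sites["true_K"] = kk
    sites["decrease_rate"] = np.where(
        sites["kinetic_class"] == "decreasing", drop / 90.0, 0.0)
    sites["baseline"] = 2.0 ** rng.normal(baseline_log2_mean,
                                          baseline_log2_sd, size=n)

    samples = design.index.to_numpy()
    times = design["time_min"].to_numpy(dtype=float)
    replicates = sorted(set(zip(design["dataset"], design["replicate"])))
    loading = pd.Series(
        np.exp(rng.normal(0.0, loading_sd, size=len(samples))),
        index=samples, name="loading_factor")
    rep_cols = [f"{ds}_rep{r}" for ds, r in replicates]
    rep_offsets = pd.DataFrame(
        np.exp(rng.normal(0.0, replicate_offset_sd, size=(n, len(replicates)))),
        index=sites.index, columns=rep_cols)
    rep_col_of_sample = {
        s: f"{design.loc[s, 'dataset']}_rep{design.loc[s, 'replicate']}"
        for s in samples}

    signal = np.empty((n, len(samples)))
    for i, (sid, row) in enumerate(sites.iterrows()):
        signal[i] = _noise_free_log2_signal(
            row["kinetic_class"], times, row["true_Vm"], row["true_K"],
            row["decrease_rate"])
    values = sites["baseline"].to_numpy()[:, None] * 2.0 ** signal
    values *= loading.to_numpy()[None, :]
    offs = np.column_stack([rep_offsets[rep_col_of_sample[s]] for s in samples])
    values *= offs
    if noise_sd > 0:
        values *= 2.0 ** rng.normal(0.0, noise_sd, size=values.shape)

    feature_meta = sites[["accession", "position", "residue"]].copy()
    if "flank" in sites.columns:
        feature_meta["flank"] = sites["flank"]
    if "true_kinase" in sites.columns:
        feature_meta["kinase"] = sites["true_kinase"]
    phospho = AbundanceMatrix(
        pd.DataFrame(values, index=sites.index, columns=samples),
        design.copy(), feature_meta)

    # protein-level matrix: flat per accession, small drifting fraction
    accs = sorted(sites["accession"].unique())
    p_base = 2.0 ** rng.normal(baseline_log2_mean + 2.0, baseline_log2_sd,
                               size=len(accs))
    drifting = rng.random(len(accs)) < protein_drift_fraction
    slopes = np.where(
        drifting,
        rng.uniform(-protein_drift_log2, protein_drift_log2, len(accs)) / 90.0,
        0.0)
    p_loading = np.exp(rng.normal(0.0, loading_sd, size=len(samples)))
    p_vals = p_base[:, None] * 2.0 ** (slopes[:, None] * times[None, :])
    p_vals = p_vals * p_loading[None, :]
    if noise_sd > 0:
        p_vals *= 2.0 ** rng.normal(0.0, noise_sd, size=p_vals.shape)
    protein = AbundanceMatrix(
        pd.DataFrame(p_vals, index=pd.Index(accs, name="feature_id"),
                     columns=samples),
        design.copy(),
        pd.DataFrame({"accession": accs, "drift_log2_per_min": slopes},
                     index=pd.Index(accs, name="feature_id")))

    truth_sites = sites[["accession", "position", "residue",
                         "kinetic_class", "true_Vm", "true_K",
                         "decrease_rate", "baseline"]].copy()
    if "true_kinase" in sites.columns:
        truth_sites["true_kinase"] = sites["true_kinase"]
    else:
        truth_sites["true_kinase"] = "none"
    truth = SyntheticTruth(truth_sites, loading, rep_offsets)
    return phospho, protein, truth


# ---------------------------------------------------------------------------
# full default scenario


@dataclass
class SimulationConfig:
    """Default synthetic scenario: an activated proline-directed kinase
    pair (CDK1/CDK2-like) whose substrates split into fast (K ~ 10 min)
    and slow (K ~ 60 min) activation kinetics, a basophilic control
    kinase with flat substrates, and a large decoy background of flat
    and linearly decreasing sites."""

    n_proteins: int = 300
    length_range: tuple = (300, 800)
    disordered_fraction: float = 0.4
    n_cdk_sites: int = 200          # split CDK1/CDK2 and fast/slow
    n_control_sites: int = 60       # basophilic kinase, flat kinetics
    n_flat_decoys: int = 1700
    n_decreasing_decoys: int = 300
    time_points: tuple = (0, 20, 40, 60, 90)
    n_replicates: int = 3
    include_single_timepoint: bool = False
    noise_sd: float = 0.1
    loading_sd: float = 0.2
    replicate_offset_sd: float = 0.15
    kinetics: KineticParams = field(default_factory=KineticParams)


@dataclass
class SimulationResult:
    proteome: list
    annotations: pd.DataFrame
    phospho: AbundanceMatrix
    protein: AbundanceMatrix
    truth: SyntheticTruth
    design: pd.DataFrame


def simulate(config: SimulationConfig | None = None,
             seed: int = 0) -> SimulationResult:
    """Run the full default scenario: proteome -> planted motifs ->
    decoys -> time-course matrices, deterministically from one seed."""
    cfg = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    s_prot, s_plant, s_decoy, s_tc = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(4)]

    proteome = generate_proteome(
        cfg.n_proteins, cfg.length_range,
        DisorderModel(disordered_fraction=cfg.disordered_fraction),
        seed=s_prot)
    per_kinase = {"CDK1": cfg.n_cdk_sites // 2,
                  "CDK2": cfg.n_cdk_sites - cfg.n_cdk_sites // 2,
                  "PKAC": cfg.n_control_sites}
    annotations, proteome = plant_kinase_sites(
        proteome,
        {"CDK1": CDK_MOTIF, "CDK2": CDK_MOTIF, "PKAC": BASOPHILIC_MOTIF},
        per_kinase, seed=s_plant)

    planted = annotations[["accession", "position", "residue"]].copy()
    planted["true_kinase"] = annotations["kinase"].to_numpy()
    is_cdk = planted["true_kinase"].isin(["CDK1", "CDK2"])
    # alternate fast/slow within the CDK substrate pool
    classes = np.where(np.arange(is_cdk.sum()) % 2 == 0, "fast", "slow")
    planted["kinetic_class"] = "flat"
    planted.loc[is_cdk, "kinetic_class"] = classes

    exclude = set(zip(planted["accession"], planted["position"]))
    decoys = sample_decoy_sites(
        proteome, cfg.n_flat_decoys + cfg.n_decreasing_decoys,
        exclude=exclude, seed=s_decoy)
    decoys["true_kinase"] = "none"
    decoys["kinetic_class"] = "flat"
    decoys.iloc[:cfg.n_decreasing_decoys,
                decoys.columns.get_loc("kinetic_class")] = "decreasing"

    sites = pd.concat([planted, decoys], ignore_index=True)
    seq_of = {p.accession: p.sequence for p in proteome}
    sites["flank"] = [extract_flank(seq_of[a], p)
                      for a, p in zip(sites["accession"], sites["position"])]

    design = make_design(cfg.time_points, cfg.n_replicates, dataset="tc")
    if cfg.include_single_timepoint:
        design = pd.concat([design, make_design((0, 90), 4, dataset="stp")])
    phospho, protein, truth = generate_timecourse(
        sites, design, noise_sd=cfg.noise_sd, seed=s_tc,
        loading_sd=cfg.loading_sd,
        replicate_offset_sd=cfg.replicate_offset_sd,
        kinetics=cfg.kinetics)
    return SimulationResult(proteome, annotations, phospho, protein, truth,
                            design)


# ---------------------------------------------------------------------------
# writers


def write_proteome_fasta(proteome: list[ProteinRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(p.sequence), id=p.accession, description="")
               for p in proteome]
    seqio_write(records, str(path), "fasta")


def read_proteome(fasta_path, disorder_path) -> list[ProteinRecord]:
    from Bio.SeqIO import parse as seqio_parse
    disorder = pd.read_csv(disorder_path, sep="\t")
    by_acc = {acc: grp.sort_values("position")["score"].to_numpy()
              for acc, grp in disorder.groupby("accession")}
    with open(fasta_path) as handle:
        return [ProteinRecord(r.id, str(r.seq), by_acc[r.id])
                for r in seqio_parse(handle, "fasta")]


def write_disorder_tsv(proteome: list[ProteinRecord], path) -> None:
    frames = [pd.DataFrame({"accession": p.accession,
                            "position": np.arange(1, len(p.sequence) + 1),
                            "score": p.disorder}) for p in proteome]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write all simulation outputs as plain TSV/FASTA files."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_proteome_fasta(result.proteome, out / "proteome.fasta")
    write_disorder_tsv(result.proteome, out / "disorder.tsv")
    result.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    result.phospho.to_tsv(out / "phospho_abundance.tsv",
                          out / "sample_design.tsv",
                          out / "phospho_features.tsv")
    result.protein.to_tsv(out / "protein_abundance.tsv",
                          out / "sample_design.tsv")
    result.truth.sites.rename_axis("site_id").to_csv(
        out / "truth_sites.tsv", sep="\t")
    result.truth.loading_factors.rename_axis("sample_id").to_csv(
        out / "truth_loading_factors.tsv", sep="\t")
    result.truth.replicate_offsets.rename_axis("site_id").to_csv(
        out / "truth_replicate_offsets.tsv", sep="\t")
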