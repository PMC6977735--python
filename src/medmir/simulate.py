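"""Synthetic data generators with truth records.

Every generator is a pure function of its configuration and seed, and each
emits a truth record of the effects it planted so downstream recovery can
be scored without re-deriving anything.  The generators emulate, at desk
scale, the study design of a paired primary/recurrent tumor cohort:

* a reference genome with CpG sites at a controlled density, genes and
  CpG-enriched islands;
* per-sample methylomes that differ between groups only inside planted
  differentially methylated intervals;
* methylation-dependent restriction sequencing reads — per CpG site a
  Poisson number of ~read-length fragments whose recognition site sits
  13-17 bp from one end, plus off-motif background reads;
* qPCR Ct matrices with planted paired expression shifts, per-batch
  offsets and censoring of high Ct values as undetected;
* clinical tables in the paired-cohort schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, InputError, SizingError
from .genome import GeneAnnotation, ReferenceGenome, revcomp
from .mirna import CtMatrix
from .reads import Read, ReadSet


@dataclass
class DmrSpec:
    """A planted differentially methylated interval: recurrent-group levels
    inside it are the baseline multiplied by ``fold`` (clipped to [0,1])."""

    contig: str
    start: int
    end: int
    fold: float


@dataclass
class MethylationProfile:
    """Per-sample methylation levels, one per reference CpG site."""

    sample_id: str
    group: str  # 'primary' or 'recurrent'
    levels: dict[str, np.ndarray]


@dataclass
class TruthRecord:
    planted_dmrs: list[DmrSpec] = field(default_factory=list)
    planted_de_mirnas: dict[str, float] = field(default_factory=dict)
    batch_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# reference + annotation


def _random_segment(rng, length: int, density: float, prev: str) -> str:
    """Sequence of exactly ``length`` bases in which every CpG is planted.

    Emission is unit-wise: with probability q = d/(1-d) a 'CG' unit,
    otherwise one base that never forms CG with its predecessor, so the
    realized CpG density concentrates around ``density``.
    """
    q = density / (1.0 - density)
    out: list[str] = []
    n = 0
    bases = np.array(list("ACGT"))
    while n < length:
        if rng.random() < q and n + 2 <= length:
            out.append("CG")
            n += 2
            prev = "G"
        else:
            choices = bases if prev != "C" else np.array(list("ACT"))
            b = str(rng.choice(choices))
            out.append(b)
            n += 1
            prev = b
    return "".join(out)


def generate_reference(
    n_contigs: int = 1,
    contig_length: int = 50_000,
    cpg_density: float = 0.02,
    n_genes: int = 10,
    n_islands: int = 5,
    seed: int = 0,
    island_density: float = 0.10,
    island_length: tuple[int, int] = (400, 800),
) -> tuple[ReferenceGenome, GeneAnnotation]:
    """Generate a reference genome and matching annotation.

    CpG sites appear at roughly ``cpg_density`` per bp genome-wide, with
    ``n_islands`` locally enriched stretches (density ``island_density``)
    per contig recorded as CpG islands; the background density is lowered
    to compensate, so the realized per-contig CpG count stays near
    ``cpg_density * contig_length``.  ``n_genes`` non-overlapping genes are
    placed per contig with random strand.
    """
    if not (0 < cpg_density <= 0.2):
        raise InputError("cpg_density must lie in (0, 0.2]")
    if contig_length < 5000:
        raise SizingError("contig_length must be >= 5000")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    gene_rows, island_rows = [], []
    slot = contig_length // max(n_genes, 1)
    if n_genes > 0 and slot < 2400:
        raise SizingError(
            f"cannot place {n_genes} genes on a {contig_length} bp contig"
        )
    for ci in range(n_contigs):
        name = f"contig{ci + 1}"
        # island layout: evenly spaced slots, jittered
        isl_slot = contig_length // max(n_islands, 1) if n_islands else contig_length
        intervals = []
        for k in range(n_islands):
            ilen = int(rng.integers(island_length[0], island_length[1] + 1))
            if isl_slot < ilen + 200:
                raise SizingError("too many islands for the contig length")
            lo = k * isl_slot + 100
            hi = (k + 1) * isl_slot - ilen - 100
            start = int(rng.integers(lo, max(hi, lo + 1)))
            intervals.append((start, start + ilen))
        total_isl = sum(e - s for s, e in intervals)
        bg_density = (cpg_density * contig_length - island_density * total_isl) / max(
            contig_length - total_isl, 1
        )
        if bg_density <= 0:
            raise SizingError(
                "island enrichment exceeds the global CpG budget; lower "
                "island_density or n_islands"
            )
        parts = []
        cursor, prev = 0, ""
        for j, (s, e) in enumerate(intervals):
            seg = _random_segment(rng, s - cursor, bg_density, prev)
            parts.append(seg)
            prev = seg[-1] if seg else prev
            isl = _random_segment(rng, e - s, island_density, prev)
            parts.append(isl)
            prev = isl[-1]
            cursor = e
            island_rows.append((f"{name}.isl{j + 1}", name, s, e))
        parts.append(_random_segment(rng, contig_length - cursor, bg_density, prev))
        contigs[name] = "".join(parts)
        # genes: one per slot, random span and strand
        for k in range(n_genes):
            max_len = slot - 400
            glen = int(rng.integers(min(2000, max_len), max_len + 1))
            start = k * slot + int(rng.integers(0, slot - glen - 200))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            gene_rows.append((f"{name}.g{k + 1}", name, strand, tss, tes))
    reference = ReferenceGenome(contigs=contigs)
    annotation = GeneAnnotation(
        genes=pd.DataFrame(gene_rows, columns=list(GeneAnnotation.GENE_COLUMNS)),
        cpg_islands=pd.DataFrame(
            island_rows, columns=list(GeneAnnotation.ISLAND_COLUMNS)
        ),
    )
    annotation.validate_against(reference)
    return reference, annotation


# ---------------------------------------------------------------------------
# methylomes


def generate_methylomes(
    reference: ReferenceGenome,
    annotation: GeneAnnotation | None,
    n_pairs: int,
    dmr_spec: list[DmrSpec] | None = None,
    baseline_beta_params: tuple[float, float] = (1.5, 3.5),
    noise_concentration: float = 50.0,
    seed: int = 0,
) -> tuple[list[MethylationProfile], TruthRecord]:
    """Paired methylomes with planted group differences.

    A baseline level per CpG site is drawn once from
    Beta(*baseline_beta_params*) and shared by all samples; each sample adds
    Beta-distributed noise around it (concentration ``noise_concentration``,
    mean preserved).  Inside each planted interval the recurrent group's
    expected level is baseline * fold, clipped to [0, 1]; everywhere else
    the two groups share the same expectation.
    """
    dmr_spec = list(dmr_spec or [])
    for d in dmr_spec:
        if d.contig not in reference.contigs:
            raise AnnotationError(f"planted DMR on unknown contig {d.contig}")
        if not (0 <= d.start < d.end <= reference.contig_length(d.contig)):
            raise AnnotationError(f"planted DMR off contig: {d}")
        if d.fold <= 0:
            raise InputError("fold effects must be > 0")
    rng = np.random.default_rng(seed)
    a, b = baseline_beta_params
    baseline = {
        contig: rng.beta(a, b, size=len(sites))
        for contig, sites in reference.cpg_sites.items()
    }
    recurrent_mean = {c: v.copy() for c, v in baseline.items()}
    for d in dmr_spec:
        sites = reference.cpg_sites[d.contig]
        lo, hi = np.searchsorted(sites, [d.start, d.end])
        recurrent_mean[d.contig][lo:hi] = np.clip(
            baseline[d.contig][lo:hi] * d.fold, 0.0, 1.0
        )
    eps = 1e-3

    def noisy(mean: np.ndarray) -> np.ndarray:
        m = np.clip(mean, eps, 1 - eps)
        if not np.isfinite(noise_concentration):
            return m.copy()  # noise-free: every sample carries the exact mean
        return rng.beta(m * noise_concentration, (1 - m) * noise_concentration)

    profiles = []
    for i in range(n_pairs):
        pid = i + 1
        profiles.append(
            MethylationProfile(
                sample_id=f"{pid}.1",
                group="primary",
                levels={c: noisy(v) for c, v in baseline.items()},
            )
        )
        profiles.append(
            MethylationProfile(
                sample_id=f"{pid}.2",
                group="recurrent",
                levels={c: noisy(v) for c, v in recurrent_mean.items()},
            )
        )
    return profiles, TruthRecord(planted_dmrs=dmr_spec, seed=seed)


# ---------------------------------------------------------------------------
# MeD-seq reads


def simulate_medseq_reads(
    profile: MethylationProfile,
    reference: ReferenceGenome,
    mean_depth: float = 10.0,
    read_length: int = 50,
    background_fraction: float = 0.05,
    seed: int = 0,
    window: tuple[int, int] = (13, 17),
) -> ReadSet:
    """Sequencing reads for one sample's methylome.

    Each CpG site emits Poisson(mean_depth * level) fragments; every read is
    the reference subsequence of ``read_length`` placed so the site's C sits
    at a uniform 1-based offset in ``window`` from the 5' or 3' end, then
    emitted forward or reverse-complemented at random.  Off-motif background
    reads (no in-window recognition site) are added so they make up roughly
    ``background_fraction`` of the output.  Read names encode the true
    origin site as sample|contig|site|serial; background reads are named
    sample|background|serial.  Sites too close to a contig edge for the
    fragment to fit are skipped.
    """
    from .reads import in_window_offset  # local import to avoid cycle at load

    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    wmin, wmax = window
    for contig, sites in reference.cpg_sites.items():
        seq = reference.contigs[contig]
        levels = profile.levels[contig]
        n_frags = rng.poisson(mean_depth * levels)
        for s, k in zip(sites, n_frags):
            s = int(s)
            for j in range(int(k)):
                o = int(rng.integers(wmin, wmax + 1))
                if rng.random() < 0.5:  # site offset from the 5' end
                    start = s - (o - 1)
                else:  # motif's last base at offset o from the 3' end
                    start = s + 1 - (read_length - o)
                if start < 0 or start + read_length > len(seq):
                    continue  # fragment would run off the contig edge
                frag = seq[start : start + read_length]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                reads.append(
                    Read(
                        read_id=f"{profile.sample_id}|{contig}|{s}|{len(reads)}",
                        sequence=frag,
                        quality="I" * read_length,
                    )
                )
    if background_fraction > 0 and reads:
        f = background_fraction
        n_bg = int(round(len(reads) * f / (1.0 - f)))
        contig_names = list(reference.contigs)
        made = 0
        attempts = 0
        while made < n_bg and attempts < 50 * max(n_bg, 1):
            attempts += 1
            contig = contig_names[int(rng.integers(len(contig_names)))]
            seq = reference.contigs[contig]
            if len(seq) < read_length:
                continue
            start = int(rng.integers(0, len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
            if in_window_offset(frag, reference.motif, wmin, wmax) is not None:
                continue  # would survive the positional filter: not background
            if rng.random() < 0.5:
                frag = revcomp(frag)
                if in_window_offset(frag, reference.motif, wmin, wmax) is not None:
                    continue
            reads.append(
                Read(
                    read_id=f"{profile.sample_id}|background|{made}",
                    sequence=frag,
                    quality="I" * read_length,
                )
            )
            made += 1
    return ReadSet(reads)


def tracks_from_profiles(
    profiles: list[MethylationProfile],
    reference: ReferenceGenome,
    mean_depth: float = 10.0,
    seed: int = 0,
) -> list["SiteCountTrack"]:
    """Site count tracks drawn directly from methylomes.

    Per sample and CpG site the count is Poisson(mean_depth * level) — the
    same count model the read simulator realizes, without materializing
    reads.  Convenient for count-level experiments (DMR calling power and
    calibration) where the read filter is not under study.
    """
    from .reads import SiteCountTrack

    rng = np.random.default_rng(seed)
    tracks = []
    for p in profiles:
        sites = {}
        total = 0
        for contig, site_pos in reference.cpg_sites.items():
            cnt = rng.poisson(mean_depth * p.levels[contig]).astype(np.int64)
            sites[contig] = (site_pos.copy(), cnt)
            total += int(cnt.sum())
        tracks.append(
            SiteCountTrack(sample_id=p.sample_id, sites=sites, library_total=total)
        )
    return tracks


# ---------------------------------------------------------------------------
# Ct matrices


def generate_ct_matrix(
    n_mirnas: int = 754,
    n_pairs: int = 27,
    n_batches: int = 3,
    de_spec: dict[str, float] | tuple[int, float] | None = None,
    batch_spec: dict[int, tuple[float, float]] | None = None,
    detect_ct_max: float = 35.0,
    noise_sd: float = 1.0,
    pair_effect_sd: float = 1.0,
    seed: int = 0,
) -> tuple[CtMatrix, TruthRecord]:
    """A TLDA-like Ct matrix with planted paired shifts and batch effects.

    Per-miRNA baseline Ct ~ Uniform(20, 34); Gaussian noise of sd
    ``noise_sd`` per well, plus a per-pair, per-miRNA random effect of sd
    ``pair_effect_sd`` shared by both samples of a pair (patient-level
    expression variability; it cancels in paired differences but makes a
    patient's two samples correlate, as real tumor pairs do).  ``de_spec``
    plants paired effects, either as a mapping miRNA id -> delta (signed)
    or as (n_planted, delta) with planted miRNAs chosen at random and
    shift directions alternating up/down — balanced differential
    expression, the condition under which global median normalization is
    unbiased.  delta is a log2 expression shift, so a positive delta
    lowers the recurrent Ct.  ``batch_spec`` maps batch index (0-based) to an
    (additive offset, scale) pair; the scale multiplies deviations from the
    miRNA baseline.  Pairs are assigned to batches in contiguous blocks so
    both samples of a pair always share a batch.  Wells with Ct above
    ``detect_ct_max`` are censored to missing.
    """
    if n_pairs < 1:
        raise SizingError("n_pairs must be >= 1")
    if n_batches > n_pairs:
        raise SizingError("n_batches cannot exceed n_pairs")
    rng = np.random.default_rng(seed)
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(n_mirnas)]
    if de_spec is None:
        planted: dict[str, float] = {}
    elif isinstance(de_spec, tuple):
        n_planted, delta = de_spec
        chosen = rng.choice(n_mirnas, size=n_planted, replace=False)
        planted = {
            mirna_ids[int(i)]: float(delta) * (1 if k % 2 == 0 else -1)
            for k, i in enumerate(chosen)
        }
    else:
        planted = {str(k): float(v) for k, v in de_spec.items()}
        unknown = set(planted) - set(mirna_ids)
        if unknown:
            raise InputError(f"de_spec names unknown miRNAs: {sorted(unknown)}")
    if batch_spec is None:
        batch_spec = {i: (0.0, 1.0) for i in range(n_batches)}

    baseline = rng.uniform(20.0, 34.0, size=n_mirnas)
    sample_ids, pair_ids, roles, batches = [], [], [], []
    pair_batch = np.repeat(
        np.arange(n_batches), int(np.ceil(n_pairs / n_batches))
    )[:n_pairs]
    for i in range(n_pairs):
        for suffix, role in ((".1", "primary"), (".2", "recurrent")):
            sample_ids.append(f"{i + 1}{suffix}")
            pair_ids.append(str(i + 1))
            roles.append(role)
            batches.append(int(pair_batch[i]))
    X = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_mirnas, len(sample_ids)))
    if pair_effect_sd > 0:
        pair_fx = rng.normal(0.0, pair_effect_sd, size=(n_mirnas, n_pairs))
        X += np.repeat(pair_fx, 2, axis=1)  # columns come in (.1, .2) pairs
    for g, mid in enumerate(mirna_ids):
        if mid in planted:
            for j, role in enumerate(roles):
                if role == "recurrent":
                    X[g, j] -= planted[mid]  # higher expression -> lower Ct
    for j, b in enumerate(batches):
        offset, scale = batch_spec.get(b, (0.0, 1.0))
        X[:, j] = baseline + scale * (X[:, j] - baseline) + offset
    values = pd.DataFrame(X, index=mirna_ids, columns=sample_ids)
    values = values.where(values <= detect_ct_max)
    samples = pd.DataFrame(
        {"pair_id": pair_ids, "role": roles, "batch": batches}, index=sample_ids
    )
    truth = TruthRecord(
        planted_de_mirnas=planted,
        batch_offsets={str(b): batch_spec[b][0] for b in batch_spec},
        seed=seed,
    )
    return CtMatrix(values=values, samples=samples), truth


# ---------------------------------------------------------------------------
# clinical tables


_LOCALIZATIONS = (
    ("upper leg", 0.44),
    ("lower leg", 0.11),
    ("retroperitoneal", 0.30),
    ("axilla", 0.04),
    ("mediastinum", 0.04),
    ("esophagus", 0.03),
    ("trunk", 0.04),
)
_MARGINS_PRIMARY = (("R0", 0.19), ("R1", 0.48), ("R2", 0.04), ("Rx", 0.29))
_MARGINS_RECURRENT = (("R0", 0.15), ("R1", 0.55), ("R2", 0.15), ("Rx", 0.15))


def generate_clinical(n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """A synthetic clinical table in the paired-cohort schema.

    Marginal distributions (age, sex ratio, localization mix, margin codes,
    time to recurrence) mirror a surgical well-differentiated liposarcoma
    cohort; the recurrent-surgery age is the primary age plus the rounded
    time to recurrence.
    """
    if n_pairs < 1:
        raise SizingError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)

    def pick(options):
        names = [o[0] for o in options]
        w = np.array([o[1] for o in options])
        return rng.choice(names, size=n_pairs, p=w / w.sum())

    age_primary = np.clip(np.round(rng.normal(58, 11, size=n_pairs)), 25, 88).astype(int)
    ttr = np.maximum(np.round(rng.lognormal(np.log(3.7), 0.85, size=n_pairs), 1), 0.1)
    age_recurrent = age_primary + np.round(ttr).astype(int)
    dmr_count = np.round(rng.lognormal(np.log(1500), 1.0, size=n_pairs)).astype(int)
    table = pd.DataFrame(
        {
            "pair_id": [str(i + 1) for i in range(n_pairs)],
            "age_primary": age_primary,
            "age_recurrent": age_recurrent,
            "sex": rng.choice(["female", "male"], size=n_pairs, p=[0.52, 0.48]),
            "localization": pick(_LOCALIZATIONS),
            "margin_primary": pick(_MARGINS_PRIMARY),
            "margin_recurrent": pick(_MARGINS_RECURRENT),
            "time_to_recurrence_years": ttr,
            "dmr_count": dmr_count,
        }
    )
    return table
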