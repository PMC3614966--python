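"""Synthetic data generators and the reference primer-mismatch panel.

Every analysis stage in this package can be exercised without downloads:
generators here emit clone libraries with planted OTU structure, template
sequences with planted primer mismatches, qPCR plates with known standard
curves, and station metadata with season-structured hydrography. All
generators are seed-deterministic: the seed lives in :class:`SimConfig`
and there is no hidden entropy.

The module also ships :func:`reference_mismatch_panel`, a static panel of
published full- or nearly full-length thaumarchaeal *accA* reference
sequences (GenBank/CAMERA metagenome contigs, fosmids and cultured
strains) with their printed mismatch patterns against the primer pair
Cren529F/Cren981R. Binding sites are reconstructed from the patterns and
embedded in scannable templates, so the whole primer-evaluation chain can
be validated against the published per-clade statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import ValidationError
from .primers import (
    CREN529F,
    CREN981R,
    DegeneratePrimer,
    MismatchPattern,
    Orientation,
    TemplateRecord,
    align_primer,
    parse_pattern,
    reconstruct_site,
    reverse_complement,
    expand_iupac,
)

__all__ = [
    "SimConfig",
    "ReferencePanel",
    "PanelRow",
    "reference_mismatch_panel",
    "SimulatedLibraries",
    "simulate_libraries",
    "simulate_templates",
    "simulate_qpcr",
    "simulate_env",
]

#: Observed clone-library sizes of the emulated survey design
#: (9 autumn + 10 summer libraries).
DEFAULT_LIBRARY_SIZES = (25, 26, 25, 34, 35, 33, 31, 36, 38, 25, 38, 37, 39, 30, 39, 30, 35, 32, 34)
DEFAULT_LIBRARY_NAMES = tuple(
    [f"autumn_{i:02d}" for i in range(1, 10)] + [f"summer_{i:02d}" for i in range(1, 11)]
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generators.

    Defaults mirror the emulated survey: 19 clone libraries of 25-39
    sequences, 59 planted OTUs with a geometrically skewed abundance
    distribution, a ~10x autumn/summer abundance effect for the
    gene-abundance simulation, a qPCR standard curve in the 90-98%
    efficiency range with Gaussian Ct noise, and season-structured
    temperature/salinity gradients.
    """

    seed: int
    library_sizes: tuple[int, ...] = DEFAULT_LIBRARY_SIZES
    library_names: tuple[str, ...] = DEFAULT_LIBRARY_NAMES
    n_otus: int = 59
    otu_distribution: str = "geometric"  # or "log-series"
    otu_shape: float = 0.10
    seed_copies_per_otu: int = 1
    intra_otu_distance: float = 0.02
    inter_otu_distance: float = 0.20
    season_effect: float = 10.0
    n_autumn_samples: int = 20
    n_summer_samples: int = 19
    qpcr_slope: float = -3.4746  # E ~ 94%
    qpcr_intercept: float = 38.0
    qpcr_ct_sigma: float = 0.15
    acca_fraction: float = 0.163  # accA:16S copy ratio of the emulated community
    acca_fraction_sigma: float = 0.15  # lognormal scatter of that ratio per station
    temp_range_autumn: tuple[float, float] = (18.0, 23.0)
    temp_range_summer: tuple[float, float] = (25.0, 30.0)
    sal_range_autumn: tuple[float, float] = (31.0, 34.5)
    sal_range_summer: tuple[float, float] = (27.0, 34.5)

    def __post_init__(self):
        if any(s < 1 for s in self.library_sizes):
            raise ValidationError("library sizes must be >= 1")
        if len(self.library_sizes) != len(self.library_names):
            raise ValidationError("library_sizes and library_names must align")
        if self.n_otus > sum(self.library_sizes):
            raise ValidationError("cannot plant more OTUs than sequences")
        if self.seed_copies_per_otu * self.n_otus > sum(self.library_sizes):
            raise ValidationError("seed copies exceed total sequences")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Reference mismatch panel
# ---------------------------------------------------------------------------

# (clade, sequence/strain name, accession, Cren529F pattern, Cren981R pattern)
# Pattern strings are in primer 5'->3' coordinates; "=" is a match and a
# letter is the template base observed opposite that primer position.
_PANEL_ROWS: tuple[tuple[str, str, str, str, str], ...] = (
    ("Shallow cluster", "Sargasso Sea metagenome 1095460025585", "AACY020784810",
     "No mismatch",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Shallow cluster", "Sargasso Sea metagenome 1096626735572", "AACY020559552",
     "No mismatch",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Shallow cluster", "Sargasso Sea metagenome IBEA_CTG_2097946", "AACY01016865",
     "= = G = = = = = = = = = = = = = = A = = C = = =",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Shallow cluster", "Sargasso Sea metagenome IBEA_CTG_2151838", "AACY01042731",
     "= = = = = = = = = = = = = = = = = = = = C = = =",
     "= = = = = = = = = A = = = = = A = = G = ="),
    ("Shallow cluster", "Sargasso Sea metagenome IBEA_CTG_2033382", "AACY01063159",
     "= = = = = = = = = = = = = = = = = = = = C = = =",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Shallow cluster", "Sargasso Sea metagenome IBEA_CTG_UAAYO84TF", "AACY01523534",
     "= = = = = = = = = = = = = = = = = = = = T = = =",
     "= = = = = = = = = = = = = = = A = C = = ="),
    ("Deep cluster", "HF4000_ANIW97P9 fosmid clone", "EU016593",
     "No mismatch", "No mismatch"),
    ("Deep cluster", "HE4000_APKG6D3 fosmid clone", "EU016643",
     "No mismatch", "No mismatch"),
    ("Deep cluster", "Marine metagenome HOTS_Contig54507", "ABEF01054507",
     "No mismatch", "No mismatch"),
    ("Deep cluster", "Marine metagenome HOTS_Contig48812", "ABEF01048812",
     "No mismatch", "No mismatch"),
    ("Group 1.1a-associated", "Gulf of Maine metagenome scf1108793271369", "JH165397",
     "= = = = = = = = = = = = = = = = = = = = T = = =",
     "= = = = = = = = = G = = = = = A = = = = ="),
    ("Group 1.1a-associated", "Gulf of Maine metagenome scf1108793271546", "JH165451",
     "= = = = = = = = = = = = = = = = = = = = T = = =",
     "= = = = = = = = = A = = T = = A = = = = ="),
    ("Group 1.1a-associated", "Nitrosopumilus maritimus SCM1", "NZ_ABEO01000001",
     "No mismatch", "No mismatch"),
    ("Group 1.1a-associated", "Nitrosopumilus salaria BD31", "NZ_AEXL01000070",
     "= = = = = = = = = = = = = = = = = A = = T = = =",
     "A = = = = = = = = A = = T = = G = = = = ="),
    ("Group 1.1a-associated", "Nitrosopumilus koreensis AR1", "CP003842",
     "= = = = = = = = = = = = = = = = = = = = C = = =",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Group 1.1a-associated", "Nitrosopumilus sp. SJ", "AJVI01000006",
     "= = = = = = = = = = = = = = = = = = = = C = = =",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Group 1.1a-associated", "Nitrosopumilus sp. AR", "AJVJ01000016",
     "= = = = = = = = = = = = = = = = = = = = C = = =",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Group 1.1a-associated", "Nitrosopumilus sediminis AR2", "CP003843",
     "= = = = = = = = C = = = = = = = = A = = T = = =",
     "= = = = = = = = = = = = = = = A = = = = ="),
    ("Group 1.1a-associated", "Nitrosoarchaeum limnia BG20", "AHJG01000246",
     "= = = = = = = = = = = = = = = = = = = = T = = =",
     "= = = = = = = = = A = = = = = G = = = = ="),
    ("Group 1.1a-associated", "Nitrosoarchaeum limnia SFB1", "NZ_CM001158",
     "= = = = = = = = = = = = = = = = = = = = T = = =",
     "C = = = = = = = = A = = = = = G = = = = ="),
    ("Group 1.1a-associated", "Nitrosoarchaeum koreensis MY1", "NZ_AFPU01000001",
     "= = = = = = = = = = = = = = = = = = = = T = = =",
     "= = = = = = = = = A = = = = = A = = = = ="),
    ("Cenarchaeum", "Cenarchaeum symbiosum", "DP000238",
     "= = C = = = = = G = = = = = = = = G = = = = = =",
     "C = = C = = = = = G = = C = = = = = = = ="),
    ("Group 1.1b", "Nitrososphaera gargensis Ga9.2", "CP002408",
     "= = = = = = = = C = = = = = = = = G = = = = = =",
     "C = = C = = = = = = = = G = = A = = G = ="),
)

_SPACER_CANDIDATES = ("C", "G", "A", "T")


def _neutral_spacer(primer: DegeneratePrimer, length: int) -> str:
    """Homopolymer spacer maximally incompatible with the primer.

    Chooses the base accepted at the fewest primer positions so that any
    window falling inside the spacer scores far above a planted site.
    """
    best = min(
        _SPACER_CANDIDATES,
        key=lambda b: sum(b in expand_iupac(c) for c in primer.sequence),
    )
    return best * length


def _embed_sites(
    record_id: str,
    sites: Mapping[str, tuple[DegeneratePrimer, str]],
    clade: str = "",
    flank: int = 12,
) -> TemplateRecord:
    """Concatenate primer-oriented binding sites into one plus-strand template.

    Forward sites go in as given; reverse sites as their reverse
    complement. Generation-time assertion: re-aligning each primer to the
    template reproduces the site's mismatch count (the spacer admits no
    better secondary site).
    """
    parts = []
    expected: list[tuple[DegeneratePrimer, int]] = []
    for primer, site in sites.values():
        spacer = _neutral_spacer(primer, flank)
        plus = site if primer.orientation is Orientation.FORWARD else reverse_complement(site)
        parts.append(spacer + plus)
        n_mis = sum(
            not (expand_iupac(t) <= expand_iupac(p))
            for p, t in zip(primer.sequence, site)
        )
        expected.append((primer, n_mis))
    parts.append(_neutral_spacer(list(sites.values())[0][0], flank))
    template = TemplateRecord(record_id, "".join(parts), clade)
    for primer, n_mis in expected:
        got = align_primer(primer, template).pattern.count
        if got != n_mis:
            raise ValidationError(
                f"spacer admits a better site for {primer.name} on {record_id}: "
                f"planted {n_mis}, scan found {got}"
            )
    return template


@dataclass(frozen=True)
class PanelRow:
    """One reference sequence of the mismatch panel."""

    clade: str
    name: str
    accession: str
    patterns: Mapping[str, MismatchPattern]  # primer name -> pattern
    template: TemplateRecord


@dataclass(frozen=True)
class ReferencePanel:
    primers: Mapping[str, DegeneratePrimer]
    rows: tuple[PanelRow, ...]

    def counts(self, clade: str, primer_name: str) -> list[int]:
        """Printed mismatch counts for one (clade, primer) group."""
        return [r.patterns[primer_name].count for r in self.rows if r.clade == clade]

    def to_frame(self) -> pd.DataFrame:
        from .primers import render_pattern

        rows = []
        for r in self.rows:
            row = {"clade": r.clade, "name": r.name, "accession": r.accession}
            for pname, pat in r.patterns.items():
                row[f"{pname}_pattern"] = render_pattern(pat)
                row[f"{pname}_mismatches"] = pat.count
            rows.append(row)
        return pd.DataFrame(rows)


def reference_mismatch_panel() -> ReferencePanel:
    """The published accA reference panel with reconstructed binding sites.

    23 reference sequences across five phylogenetic groups, each with its
    printed mismatch pattern against Cren529F and Cren981R. Binding sites
    reconstructed from the patterns are embedded in scannable templates;
    internal consistency (pattern count reproduced by a fresh scan) is
    asserted at load time for every row and primer.
    """
    primers = {p.name: p for p in (CREN529F, CREN981R)}
    rows = []
    for clade, name, accession, f_str, r_str in _PANEL_ROWS:
        patterns = {
            CREN529F.name: parse_pattern(f_str, CREN529F),
            CREN981R.name: parse_pattern(r_str, CREN981R),
        }
        sites = {
            pname: (primers[pname], reconstruct_site(primers[pname], pat))
            for pname, pat in patterns.items()
        }
        template = _embed_sites(accession, sites, clade)
        rows.append(PanelRow(clade, name, accession, patterns, template))
    return ReferencePanel(primers, tuple(rows))


# ---------------------------------------------------------------------------
# Clone-library simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedLibraries:
    """Planted clone-library design and its derived inputs."""

    otu_table: pd.DataFrame  # planted sample x OTU counts
    membership: Mapping[str, str]  # sequence id -> sample
    distances: DistanceMatrix  # sequence-level distances
    planted_otu: Mapping[str, str]  # sequence id -> planted OTU label


def _otu_abundances(cfg: SimConfig) -> np.ndarray:
    k = cfg.n_otus
    if cfg.otu_distribution == "geometric":
        w = cfg.otu_shape * (1 - cfg.otu_shape) ** np.arange(k)
    elif cfg.otu_distribution == "log-series":
        x = 1 - cfg.otu_shape
        w = x ** np.arange(1, k + 1) / np.arange(1, k + 1)
    else:
        raise ValidationError(f"unknown otu_distribution {cfg.otu_distribution!r}")
    return w / w.sum()


def simulate_libraries(cfg: SimConfig) -> SimulatedLibraries:
    """Draw clone libraries from a skewed OTU abundance distribution.

    True OTU relative abundances follow the configured distribution; each
    library is a multinomial sample. ``seed_copies_per_otu`` copies of
    every OTU are placed round-robin first, guaranteeing each planted OTU
    is observed (>= 2 copies per OTU forces a singleton-free design).
    Sequence-level distances are consistent with the planted partition:
    ``intra_otu_distance`` within OTUs and ``inter_otu_distance`` between,
    so furthest-neighbor clustering at any cutoff between the two recovers
    the planted OTUs exactly.
    """
    rng = cfg.rng()
    probs = _otu_abundances(cfg)
    otu_labels = [f"OTU{i + 1:03d}" for i in range(cfg.n_otus)]
    sizes = dict(zip(cfg.library_names, cfg.library_sizes))
    counts = pd.DataFrame(0, index=list(cfg.library_names), columns=otu_labels, dtype=int)

    # guaranteed coverage: round-robin seed copies
    lib_cycle = list(cfg.library_names)
    slot = 0
    remaining = dict(sizes)
    for _ in range(cfg.seed_copies_per_otu):
        for otu in otu_labels:
            for _ in range(len(lib_cycle)):
                lib = lib_cycle[slot % len(lib_cycle)]
                slot += 1
                if remaining[lib] > 0:
                    counts.loc[lib, otu] += 1
                    remaining[lib] -= 1
                    break
            else:
                raise ValidationError("infeasible design: libraries too small for seed copies")

    for lib in cfg.library_names:
        if remaining[lib] > 0:
            counts.loc[lib] += rng.multinomial(remaining[lib], probs)

    # materialize sequences and the planted-consistent distance matrix
    seq_ids, membership, planted = [], {}, {}
    for lib in cfg.library_names:
        i = 0
        for otu in otu_labels:
            for _ in range(int(counts.loc[lib, otu])):
                i += 1
                sid = f"{lib}_c{i:03d}"
                seq_ids.append(sid)
                membership[sid] = lib
                planted[sid] = otu
    otu_idx = np.array([otu_labels.index(planted[s]) for s in seq_ids])
    same = otu_idx[:, None] == otu_idx[None, :]
    d = np.where(same, cfg.intra_otu_distance, cfg.inter_otu_distance)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(d, seq_ids)

    observed = counts.loc[:, (counts.sum(axis=0) > 0)]
    return SimulatedLibraries(observed, membership, dm, planted)


# ---------------------------------------------------------------------------
# Template simulation with planted primer mismatches
# ---------------------------------------------------------------------------


def _planted_pattern(
    primer: DegeneratePrimer, n_mismatches: int, rng: np.random.Generator
) -> MismatchPattern:
    """Random pattern with exactly ``n_mismatches`` incompatible bases."""
    if n_mismatches > len(primer) // 3:
        raise ValidationError(
            f"cannot plant {n_mismatches} mismatches in a {len(primer)}-nt primer "
            f"(limit {len(primer) // 3})"
        )
    candidates = [i for i, c in enumerate(primer.sequence) if len(expand_iupac(c)) < 4]
    if len(candidates) < n_mismatches:
        raise ValidationError("not enough non-degenerate positions to plant mismatches")
    positions = rng.choice(len(candidates), size=n_mismatches, replace=False)
    tokens = ["="] * len(primer)
    for p in positions:
        i = candidates[int(p)]
        incompatible = sorted(set("ACGT") - expand_iupac(primer.sequence[i]))
        tokens[i] = incompatible[int(rng.integers(len(incompatible)))]
    return MismatchPattern(primer.name, tuple(tokens))


def simulate_templates(
    cfg: SimConfig,
    primer: DegeneratePrimer,
    planted: Mapping[str, Sequence[int]],
) -> tuple[list[TemplateRecord], dict[str, int]]:
    """Templates with exactly one best binding site per sequence.

    ``planted`` maps a clade label to the mismatch counts to plant, one
    template per count. Returns the records plus the id -> planted-count
    bookkeeping map. Decoy-freedom is asserted at generation time.
    """
    rng = cfg.rng()
    records, truth = [], {}
    for clade, counts in planted.items():
        for j, k in enumerate(counts, start=1):
            pattern = _planted_pattern(primer, int(k), rng)
            site = reconstruct_site(primer, pattern)
            rid = f"{clade}_t{j:03d}"
            record = _embed_sites(rid, {primer.name: (primer, site)}, clade)
            records.append(record)
            truth[rid] = int(k)
    return records, truth


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(
    cfg: SimConfig,
    genes: Sequence[str] = ("16S", "accA"),
    n_standard_levels: int = 5,
    top_standard: float = 1e7,
    base_copies: float = 1e4,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Simulate a qPCR plate: dilution standards plus seasonal unknowns.

    Standards are a 10-fold series (``n_standard_levels`` levels from
    ``top_standard`` down) in triplicate per gene. Unknown samples are
    surface stations of both seasons; each station has one latent
    community abundance around ``base_copies`` (autumn stations scaled by
    ``season_effect``, lognormal station scatter), the 16S gene tracks it
    directly and the accA gene carries ``acca_fraction`` of it with extra
    per-station lognormal scatter — so the two genes are correlated and
    their ratio centers on the configured fraction. Ct values follow the
    configured standard curve plus Gaussian noise. Returns the plate table
    and the planted per-(sample, gene) copy numbers per reaction.
    """
    rng = cfg.rng()
    rows = []
    planted: dict[tuple[str, str], float] = {}
    for gene in genes:
        for level in range(n_standard_levels):
            copies = top_standard / 10**level
            for rep in range(1, 4):
                ct = cfg.qpcr_intercept + cfg.qpcr_slope * np.log10(copies)
                ct += rng.normal(0, cfg.qpcr_ct_sigma)
                rows.append(
                    {"sample": f"std_{gene}_{level}", "gene": gene, "replicate": rep,
                     "ct": ct, "role": "standard", "known_copies": copies}
                )
    samples = [f"autumn_st{i:02d}" for i in range(1, cfg.n_autumn_samples + 1)] + [
        f"summer_st{i:02d}" for i in range(1, cfg.n_summer_samples + 1)
    ]
    for sample in samples:
        seasonal = cfg.season_effect if sample.startswith("autumn") else 1.0
        latent = base_copies * seasonal * rng.lognormal(0, 0.5)
        for gene in genes:
            if gene == "accA":
                copies = latent * cfg.acca_fraction * rng.lognormal(0, cfg.acca_fraction_sigma)
            else:
                copies = latent
            planted[(sample, gene)] = copies
            for rep in range(1, 4):
                ct = cfg.qpcr_intercept + cfg.qpcr_slope * np.log10(copies)
                ct += rng.normal(0, cfg.qpcr_ct_sigma)
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep,
                     "ct": ct, "role": "unknown", "known_copies": np.nan}
                )
    return pd.DataFrame(rows), planted


# ---------------------------------------------------------------------------
# Environmental metadata simulation
# ---------------------------------------------------------------------------


def simulate_env(
    cfg: SimConfig,
    link_strength: float = 0.0,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, DistanceMatrix]:
    """Station metadata plus a community matrix with a planted env link.

    One row per clone library: season, depth, temperature, salinity and
    coordinates drawn from season-specific ranges (summer warmer, estuary
    fresher). The returned community distance matrix is built as
    ``link_strength``·(scaled environmental distance) plus lognormal-free
    Gaussian noise folded to stay non-negative; ``link_strength = 0``
    yields a community structure independent of the environment (a null),
    larger values plant a monotone dependence for power studies.
    """
    if not (0 <= link_strength <= 1):
        raise ValidationError("link_strength must be in [0, 1]")
    rng = cfg.rng()
    rows = []
    for name in cfg.library_names:
        autumn = name.startswith("autumn")
        t_lo, t_hi = cfg.temp_range_autumn if autumn else cfg.temp_range_summer
        s_lo, s_hi = cfg.sal_range_autumn if autumn else cfg.sal_range_summer
        rows.append(
            {
                "sample": name,
                "season": "autumn" if autumn else "summer",
                "depth_m": float(rng.choice([0, 10, 25, 40, 50, 75])),
                "temperature": float(rng.uniform(t_lo, t_hi)),
                "salinity": float(rng.uniform(s_lo, s_hi)),
                "latitude": float(rng.uniform(27.0, 32.0)),
                "longitude": float(rng.uniform(121.0, 127.0)),
            }
        )
    env = pd.DataFrame(rows).set_index("sample")

    from .ecostats import env_distance

    ed = env_distance(env, ("temperature", "salinity")).data
    scale = ed.max() if ed.max() > 0 else 1.0
    n = len(env)
    noise = np.abs(rng.normal(0.5, noise_sd, size=(n, n)))
    noise = (noise + noise.T) / 2
    d = link_strength * ed / scale + (1 - link_strength) * noise
    np.fill_diagonal(d, 0.0)
    return env, DistanceMatrix(d, list(env.index))
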