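"""Run configuration shared across pipeline stages.

All thresholds that the pipeline applies live here so that a run is fully
described by one object. Defaults correspond to the canonical CfERV-Fc1(a)
analysis conditions: a 457-bp LTR, 5-bp target-site duplications, the canine
neutral substitution rate, and the published discovery/genotyping filters.
"""

from dataclasses import dataclass, field


#: Canine neutral substitution rate, changes per site per year.
CANINE_RATE = 1.33e-9
#: "Average mammalian" neutral rate, an alternative clock calibration.
MAMMALIAN_RATE = 2.2e-9
#: Mouse neutral rate, the fastest calibration considered.
MOUSE_RATE = 4.5e-9


@dataclass
class RunConfig:
    """Parameters for a full discovery → genotyping → dating run.

    Attributes
    ----------
    rate_per_site_year : float
        Neutral substitution rate used by the LTR molecular clock
        (changes per site per year).
    ltr_length : int
        Canonical LTR length of the element family, in bp.
    tsd_length : int
        Target-site duplication length created at integration.
    flank_bp : int
        Genomic flank taken on each side of a breakpoint when
        reconstructing insertion/pre-insertion alleles.
    min_support_pairs : int
        Minimum anchored read pairs required to emit a candidate locus.
    known_erv_exclusion_bp : int
        Candidates within this distance of an annotated element of the
        queried family are dropped as rediscoveries.
    assembly_window_bp : int
        Window around a candidate breakpoint from which reads are pulled
        into junction assembly.
    min_junction_bp : int
        Minimum assembled LTR-derived and genomic sequence (each) for a
        contig to qualify as an LTR-genome junction.
    deletion_mad_cutoff : float
        Insert sizes above median + cutoff x MAD are deletion-supporting.
    deletion_min_mapq : int
        Both mates of a deletion-supporting pair must map at or above
        this quality.
    solo_size_range, provirus_size_range : tuple
        Deletion sizes consistent with a solo LTR or a full provirus.
    permutations : int
        Number of shuffled insertion sets for the genic-depletion test.
    windows_kb : tuple
        Gene-proximity window sizes tested, in kb.
    seed : int
        Seed for every stochastic step of a run.
    """

    rate_per_site_year: float = CANINE_RATE
    ltr_length: int = 457
    tsd_length: int = 5
    flank_bp: int = 600
    min_support_pairs: int = 2
    known_erv_exclusion_bp: int = 500
    assembly_window_bp: int = 200
    min_junction_bp: int = 30
    deletion_mad_cutoff: float = 7.0
    deletion_min_mapq: int = 20
    solo_size_range: tuple = (400, 500)
    provirus_size_range: tuple = (7000, 9000)
    permutations: int = 1000
    windows_kb: tuple = (0, 5, 10, 25, 50, 100)
    seed: int = 0

    def __post_init__(self):
        if self.rate_per_site_year <= 0:
            raise ValueError("substitution rate must be positive")
        if self.ltr_length <= 0 or self.tsd_length <= 0:
            raise ValueError("lengths must be positive")
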