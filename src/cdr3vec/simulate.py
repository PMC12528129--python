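"""Synthetic CDR3 repertoires with controllable cohort topology.

Real TCRβ repertoires differ between clinical groups in how many motif
families they contain and how noisy each family is: healthy controls look
tight and conserved, ARDS repertoires diffuse and fragmented, other ICU
(non-ARDS) repertoires intermediate. The generator emulates exactly that
contrast: a cohort is a set of template CDR3s ("motif families") from
which member sequences are copied with i.i.d. per-position substitutions,
plus an optional fraction of fully random background sequences.

All sequences satisfy the curation invariants by construction — they
start with the conserved C, end with F or G, use only the 20 standard
amino acids, and have lengths drawn from a truncated normal centred near
the canonical 15 residues. Generation is fully determined by the seed.

Interior residues are drawn from a skewed amino-acid frequency typical
of TCRβ CDR3 loops (glycine/serine-rich) rather than uniformly: real
CDR3 junctions occupy a strongly restricted trigram space, which is what
lets an embedding vocabulary trained on one cohort cover the others. A
uniform 20-letter alphabet would make cohort trigram sets nearly
disjoint — a structure no real repertoire shows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ClonotypeRecord

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: approximate interior residue usage of TCRβ CDR3 loops (junctions are
#: Gly/Ser-rich from D-segment and N-addition biases); renormalized below
_CDR3_FREQS = {
    "G": 0.35, "S": 0.30, "L": 0.12, "A": 0.08, "E": 0.05, "T": 0.03,
    "Q": 0.02, "Y": 0.015, "R": 0.01, "D": 0.008, "N": 0.005, "P": 0.004,
    "V": 0.003, "F": 0.002, "I": 0.002, "H": 0.001, "K": 0.001,
    "W": 0.0005, "M": 0.0003, "C": 0.0002,
}
_AA_P = np.array([_CDR3_FREQS[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()


@dataclass
class CohortProfile:
    """Recipe for one synthetic cohort.

    mutation_rate is the per-interior-position substitution probability
    applied when copying a template; background_fraction is the share of
    sequences drawn fully at random instead of from a family. Boundary
    residues (the leading C and trailing F/G) are never mutated.
    """

    name: str
    n_sequences: int
    n_motif_families: int
    mutation_rate: float
    background_fraction: float = 0.0
    length_mean: float = 15.0
    length_sd: float = 2.0
    length_min: int = 8
    length_max: int = 22
    seed: int = 0
    sample_id: str | None = None

    def validate(self) -> None:
        if self.n_sequences < 1 or self.n_motif_families < 1:
            raise ValueError("n_sequences and n_motif_families must be >= 1")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if not 3 <= self.length_min <= self.length_max:
            raise ValueError("need 3 <= length_min <= length_max")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")


def _draw_length(rng: np.random.Generator, p: CohortProfile) -> int:
    """Truncated-normal length, rounded to an integer within bounds."""
    if p.length_sd == 0:
        return int(round(min(max(p.length_mean, p.length_min), p.length_max)))
    for _ in range(1000):
        val = int(round(rng.normal(p.length_mean, p.length_sd)))
        if p.length_min <= val <= p.length_max:
            return val
    raise ValueError("length distribution rejects all draws; check bounds")


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    interior = rng.choice(_AA, size=length - 2, p=_AA_P)
    end = rng.choice(["F", "G"])
    return "C" + "".join(interior) + end


def _substitute(rng: np.random.Generator, current: str) -> str:
    choices = _AA[_AA != current]
    return str(rng.choice(choices))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute interior positions i.i.d. at ``rate``; boundaries kept.

    Every family member carries at least one substitution (clonotype
    tables list unique rearrangements, so exact duplicates of a template
    would not appear as separate rows), unless ``rate`` is exactly 0 —
    the degenerate all-identical mode used for testing.
    """
    if rate == 0:
        return seq
    chars = list(seq)
    mutated = 0
    for i in range(1, len(chars) - 1):
        if rng.random() < rate:
            chars[i] = _substitute(rng, chars[i])
            mutated += 1
    if mutated == 0:
        i = int(rng.integers(1, len(chars) - 1))
        chars[i] = _substitute(rng, chars[i])
    return "".join(chars)


def generate_cohort(profile: CohortProfile) -> list[ClonotypeRecord]:
    """Generate one cohort of curate-clean clonotype records.

    Templates are drawn first (one per motif family); each sequence is
    then either a mutated copy of a uniformly chosen template or, with
    probability ``background_fraction``, a fully random CDR3. The V-gene
    field records the family of origin (metadata only).
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    templates = [_random_cdr3(rng, _draw_length(rng, profile))
                 for _ in range(profile.n_motif_families)]
    sample = profile.sample_id if profile.sample_id is not None else profile.name
    records = []
    for i in range(profile.n_sequences):
        if rng.random() < profile.background_fraction:
            seq = _random_cdr3(rng, _draw_length(rng, profile))
            v_gene = "TRBV0"
        else:
            fam = int(rng.integers(profile.n_motif_families))
            seq = _mutate(rng, templates[fam], profile.mutation_rate)
            v_gene = f"TRBV{fam + 1}"
        records.append(ClonotypeRecord(
            sequence_id=f"{profile.name}_{i + 1:04d}", cdr3_aa=seq,
            v_gene=v_gene, productive=True, sample_id=sample,
            group=profile.name))
    return records


def preset_profiles(seed: int = 0) -> dict[str, CohortProfile]:
    """The three study-condition cohorts.

    Sizes are 254 control / 139 ARDS / 115 non-ARDS (508 sequences in
    total). Family counts mirror the cluster counts characteristic of
    each group (5 / 9 / 2), and the noise settings produce the tight /
    diffuse / intermediate topologies: controls are low-mutation with no
    background, the ARDS-like cohort is high-mutation with a 20%% random
    background, the non-ARDS-like cohort sits between.
    """
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    return {
        "control": CohortProfile(name="control", n_sequences=254,
                                 n_motif_families=5, mutation_rate=0.02,
                                 background_fraction=0.0, seed=int(seeds[0])),
        "ards": CohortProfile(name="ards", n_sequences=139,
                              n_motif_families=9, mutation_rate=0.15,
                              background_fraction=0.20, seed=int(seeds[1])),
        "non_ards": CohortProfile(name="non_ards", n_sequences=115,
                                  n_motif_families=2, mutation_rate=0.05,
                                  background_fraction=0.05, seed=int(seeds[2])),
    }


def generate_presets(seed: int = 0) -> list[ClonotypeRecord]:
    """All three preset cohorts merged, group-tagged, in control/ards/non_ards order."""
    records = []
    for profile in preset_profiles(seed).values():
        records.extend(generate_cohort(profile))
    return records
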