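"""Synthetic TCR-pMHC repertoires with tunable, per-feature binding signal.

The generator emulates the schema and missingness structure of curated
specificity databases: every record is a positive (binding) pair; alpha
chains are jointly missing at a configurable rate; V/J gene calls and MHC
alleles come from small fixed universes. Binding signal is implanted per
feature so downstream models have a known ground truth to recover:

* sequence signal -- each peptide owns a designated 3-mer motif; with
  probability ``beta_motif_rate`` the motif is implanted at a random
  interior position of the binder's CDR3beta (``alpha_motif_rate``
  analogously for CDR3alpha);
* gene signal -- with probability ``vgene_bias`` a binder's Vbeta is the
  peptide's designated gene rather than a uniform draw;
* MHC signal -- analogous via ``mhc_bias`` and a designated allele.

CDR3 backgrounds are i.i.d. uniform residues between fixed C...F anchors
with lengths uniform on [10, 19], compatible with the 28-residue cap of the
fixed-length autoencoder. Negatives are never generated here; they come
from the pair-mismatching sampler, as in the source databases which contain
only positive pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ABSENT, AMINO_ACIDS, PairRecord

DEFAULT_PEPTIDES = (
    "LPRRSGAAGA", "GILGFVFTL", "NLVPMVATV", "GLCTLVAML", "SSYRRPVGI",
)

V_BETA_UNIVERSE = tuple(f"TRBV{i}" for i in range(1, 13))
J_BETA_UNIVERSE = tuple(f"TRBJ{i}" for i in range(1, 9))
V_ALPHA_UNIVERSE = tuple(f"TRAV{i}" for i in range(1, 11))
J_ALPHA_UNIVERSE = tuple(f"TRAJ{i}" for i in range(1, 7))
MHC_UNIVERSE = ("HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02",
                "HLA-B*08:01", "HLA-A*24:02", "HLA-DRB1*04:01")


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth description of one synthetic repertoire."""

    peptides: tuple[str, ...] = DEFAULT_PEPTIDES
    beta_motif_rate: float = 0.9
    alpha_motif_rate: float = 0.0
    vgene_bias: float = 0.0
    mhc_bias: float = 0.0
    alpha_missing_rate: float = 0.5
    n_pairs: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("beta_motif_rate", "alpha_motif_rate", "vgene_bias",
                     "mhc_bias", "alpha_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_pairs < 1:
            raise ValueError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if len(self.peptides) < 1:
            raise ValueError("at least one peptide required")
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("peptides must be distinct")

    def designated_motifs(self) -> dict[str, str]:
        """Peptide -> its 3-mer motif, drawn deterministically per spec seed."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        motifs: dict[str, str] = {}
        used: set[str] = set()
        for pep in self.peptides:
            while True:
                m = "".join(rng.choice(list(AMINO_ACIDS), size=3))
                if m not in used:
                    used.add(m)
                    motifs[pep] = m
                    break
        return motifs

    def designated_vbeta(self) -> dict[str, str]:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 102]))
        order = rng.permutation(len(V_BETA_UNIVERSE))
        return {pep: V_BETA_UNIVERSE[order[i % len(V_BETA_UNIVERSE)]]
                for i, pep in enumerate(self.peptides)}

    def designated_mhc(self) -> dict[str, str]:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 103]))
        order = rng.permutation(len(MHC_UNIVERSE))
        return {pep: MHC_UNIVERSE[order[i % len(MHC_UNIVERSE)]]
                for i, pep in enumerate(self.peptides)}


def _random_cdr3(rng: np.random.Generator) -> str:
    n_inner = rng.integers(8, 18)  # total length uniform on [10, 19]
    inner = "".join(rng.choice(list(AMINO_ACIDS), size=n_inner))
    return "C" + inner + "F"


def _implant(cdr3: str, motif: str, rng: np.random.Generator) -> str:
    """Overwrite a random interior window (anchors preserved) with the motif."""
    start = int(rng.integers(1, len(cdr3) - 1 - len(motif) + 1))
    return cdr3[:start] + motif + cdr3[start + len(motif):]


def generate_repertoire(spec: SignalSpec) -> list[PairRecord]:
    """Draw ``spec.n_pairs`` positive pairs with the implanted signal.

    Fully reproducible from ``spec.seed``; two calls with equal specs return
    identical record lists.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    motifs = spec.designated_motifs()
    vbeta_of = spec.designated_vbeta()
    mhc_of = spec.designated_mhc()
    peptides = list(spec.peptides)
    records: list[PairRecord] = []
    for _ in range(spec.n_pairs):
        pep = peptides[int(rng.integers(len(peptides)))]
        beta = _random_cdr3(rng)
        if rng.random() < spec.beta_motif_rate:
            beta = _implant(beta, motifs[pep], rng)
        if rng.random() < spec.vgene_bias:
            v_beta = vbeta_of[pep]
        else:
            v_beta = V_BETA_UNIVERSE[int(rng.integers(len(V_BETA_UNIVERSE)))]
        j_beta = J_BETA_UNIVERSE[int(rng.integers(len(J_BETA_UNIVERSE)))]
        if rng.random() < spec.mhc_bias:
            mhc = mhc_of[pep]
        else:
            mhc = MHC_UNIVERSE[int(rng.integers(len(MHC_UNIVERSE)))]
        t_type = "CD8" if rng.random() < 0.7 else "CD4"
        # draw the alpha chain before deciding missingness so the record
        # stream consumed from the generator is independent of the rate
        alpha = _random_cdr3(rng)
        if rng.random() < spec.alpha_motif_rate:
            alpha = _implant(alpha, motifs[pep], rng)
        v_alpha = V_ALPHA_UNIVERSE[int(rng.integers(len(V_ALPHA_UNIVERSE)))]
        j_alpha = J_ALPHA_UNIVERSE[int(rng.integers(len(J_ALPHA_UNIVERSE)))]
        if rng.random() < spec.alpha_missing_rate:
            alpha, v_alpha, j_alpha = ABSENT, ABSENT, ABSENT
        records.append(PairRecord(
            cdr3_beta=beta, peptide=pep, label=1, cdr3_alpha=alpha,
            v_beta=v_beta, j_beta=j_beta, v_alpha=v_alpha, j_alpha=j_alpha,
            mhc=mhc, t_cell_type=t_type))
    return records


def signal_free_permutation(records: list[PairRecord], seed: int) -> list[PairRecord]:
    """Destroy all TCR-peptide association while preserving marginals.

    The pMHC side (peptide, MHC) is permuted as a unit against the TCR side,
    producing a null repertoire on which any predictor has expected AUC 0.5.
    """
    if not records:
        raise ValueError("cannot permute an empty record list")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    out = []
    for rec, j in zip(records, perm):
        donor = records[j]
        out.append(PairRecord(
            cdr3_beta=rec.cdr3_beta, cdr3_alpha=rec.cdr3_alpha,
            v_beta=rec.v_beta, j_beta=rec.j_beta,
            v_alpha=rec.v_alpha, j_alpha=rec.j_alpha,
            t_cell_type=rec.t_cell_type,
            peptide=donor.peptide, mhc=donor.mhc, label=rec.label))
    return out
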