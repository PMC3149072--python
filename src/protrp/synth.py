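"""Synthetic datasets with planted tandem-repeat protein structure.

Generates protein families built from a repeated motif (parameterized
copy number and per-residue substitution rate), optionally prefixed with
a signal-peptide-like hydrophobic leader, plus repeat-free decoys, the
matching secretion-annotation table, and a ground-truth table keyed by
the same sequence ids.  Proteins can also be reverse-translated into
EST-like nucleotide records to exercise the translation and ORF stages.

The default family specs emulate extensin-like Ser-Pro4 repeat proteins:
Pro-rich motifs of period 8-11, tens of copies per domain, and a few
percent of point substitutions — the regime in which plant secretome
repeat screens operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .seqio import AMINO_ACIDS, SequenceRecord, SourceTier

#: background residue frequencies for leaders/tails (rounded database
#: composition of plant proteins; renormalized at use)
BACKGROUND_FREQUENCIES = {
    "A": 0.079, "C": 0.015, "D": 0.053, "E": 0.063, "F": 0.040,
    "G": 0.071, "H": 0.022, "I": 0.053, "K": 0.058, "L": 0.091,
    "M": 0.022, "N": 0.043, "P": 0.048, "Q": 0.040, "R": 0.051,
    "S": 0.068, "T": 0.054, "V": 0.066, "W": 0.013, "Y": 0.032,
}

_HYDROPHOBIC = "AILMFVW"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


@dataclass
class MotifFamilySpec:
    """One planted motif family.

    ``substitution_rate`` is the i.i.d. per-residue substitution
    probability applied to the repeated motif copies; substitutions draw
    from the 19 other standard residues and never introduce ``X`` or
    ``*``.  ``variant_rate`` is the per-residue probability of a
    member-specific substitution in the base motif itself, emulating the
    between-sequence divergence of a repeat family; variant
    substitutions leave the proline backbone untouched (they neither hit
    nor introduce proline), matching the conservation of Pro positions
    in hydroxyproline-rich repeat families and guaranteeing that every
    planted domain stays as Pro-rich as its base motif.
    """

    motif: str = "SPPPPYVYK"
    members: int = 30
    copies_range: tuple[int, int] = (6, 12)
    substitution_rate: float = 0.05
    variant_rate: float = 0.0
    signal_peptide: bool = True
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4 to be clusterable")
        if not 0.0 <= self.substitution_rate < 0.3:
            raise ValueError("substitution_rate must be in [0, 0.3)")
        if not 0.0 <= self.variant_rate < 0.3:
            raise ValueError("variant_rate must be in [0, 0.3)")
        if self.copies_range[0] > self.copies_range[1]:
            raise ValueError("copies_range must be (min, max)")
        if not self.name:
            self.name = self.motif


@dataclass
class TruthRecord:
    """Ground truth for one planted protein."""

    id: str
    family: str
    motif: str
    variant_motif: str
    domain_start: int
    domain_end: int
    period: int
    copies: int
    secreted: bool


def _draw_background(rng: np.random.Generator, n: int) -> str:
    letters = list(BACKGROUND_FREQUENCIES)
    p = np.array([BACKGROUND_FREQUENCIES[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def _mutate(motif_copies: str, rate: float,
            rng: np.random.Generator) -> str:
    if rate <= 0:
        return motif_copies
    out = list(motif_copies)
    hits = rng.random(len(out)) < rate
    for j in np.nonzero(hits)[0]:
        choices = [a for a in AMINO_ACIDS if a != out[j]]
        out[j] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _member_variant(motif: str, rate: float,
                    rng: np.random.Generator) -> str:
    """Member-specific motif variant; proline positions are conserved
    and proline is never introduced."""
    if rate <= 0:
        return motif
    out = list(motif)
    hits = rng.random(len(out)) < rate
    for j in np.nonzero(hits)[0]:
        if out[j] == "P":
            continue
        choices = [a for a in AMINO_ACIDS if a not in (out[j], "P")]
        out[j] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def make_tr_protein(spec: MotifFamilySpec, index: int
                    ) -> tuple[SequenceRecord, TruthRecord]:
    """One planted TR protein, deterministic under ``(spec.seed, index)``.

    Layout: ``M`` + 19-residue hydrophobic-core leader (when
    ``signal_peptide``) + mutated tandem copies of a member-specific
    motif variant + background tail.
    """
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, index])
    if spec.signal_peptide:
        core = "".join(rng.choice(list(_HYDROPHOBIC), size=12))
        leader = "M" + _draw_background(rng, 3) + core + _draw_background(
            rng, 4)
    else:
        leader = "M" + _draw_background(rng, 4)
    lo, hi = spec.copies_range
    copies = int(rng.integers(lo, hi + 1))
    variant = _member_variant(spec.motif, spec.variant_rate, rng)
    domain = _mutate(variant * copies, spec.substitution_rate, rng)
    tail = _draw_background(rng, int(rng.integers(5, 21)))
    seq = leader + domain + tail
    rid = f"{spec.name}_{index:03d}"
    rec = SequenceRecord(id=rid, sequence=seq, source_tier=SourceTier.TC,
                         species=f"sp{index % 12:02d}")
    truth = TruthRecord(
        id=rid, family=spec.name, motif=spec.motif,
        variant_motif=variant,
        domain_start=len(leader), domain_end=len(leader) + len(domain),
        period=len(spec.motif), copies=copies, secreted=spec.signal_peptide)
    return rec, truth


def make_decoy(seed: int, index: int, length_range=(80, 200)
               ) -> SequenceRecord:
    """A repeat-free background protein."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 1_000_000 + index])
    n = int(rng.integers(*length_range))
    seq = "M" + _draw_background(rng, n)
    return SequenceRecord(id=f"decoy_{index:03d}", sequence=seq,
                          source_tier=SourceTier.TC,
                          species=f"sp{index % 12:02d}")


def reverse_translate(protein: str, rng: np.random.Generator,
                      error_rate: float = 0.0, add_stop: bool = True
                      ) -> str:
    """EST-like nucleotide encoding of a protein: random synonymous
    codons, optional stop codon, and i.i.d. per-base errors."""
    nt = []
    for aa in protein:
        codons = _CODONS_BY_AA[aa]
        nt.append(codons[int(rng.integers(len(codons)))])
    if add_stop:
        nt.append(_STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))])
    s = list("".join(nt))
    if error_rate > 0:
        hits = rng.random(len(s)) < error_rate
        for j in np.nonzero(hits)[0]:
            s[j] = "ACGT"[int(rng.integers(4))]
    return "".join(s)


def default_family_specs(seed: int = 0, members: int = 30,
                         substitution_rate: float = 0.05,
                         variant_rate: float = 0.0
                         ) -> list[MotifFamilySpec]:
    """Five Pro-rich motif families spanning the common repeat
    architectures: extensin-like SPn, PRP-like PPVYK, PELPK-like, and
    hybrid-domain motifs.

    With the default ``variant_rate`` of 0 every member repeats the
    family's base motif (plus per-copy substitution noise); a nonzero
    rate diversifies members into motif variants, emulating corpora in
    which nearly every sequence carries a distinct consensus.  Two of
    the five base motifs (PPVEKPVYK, PPPVPVYKKPL) share PVYK-type
    crosslinking content, so their clusters are compositional
    neighbours, as related repeat classes are in real secretomes.
    """
    motifs = ["SPPPPYVYK", "PPVEKPVYK", "PELPKPVP", "PPVTLPPVVK",
              "PPPVPVYKKPL"]
    return [MotifFamilySpec(motif=m, members=members,
                            substitution_rate=substitution_rate,
                            variant_rate=variant_rate,
                            signal_peptide=True, seed=seed + 17 * k,
                            name=f"fam{k}")
            for k, m in enumerate(motifs)]


def make_dataset(specs: list[MotifFamilySpec], decoys: int = 0,
                 seed: int = 0, outdir: str | Path | None = None,
                 as_nucleotide: bool = False,
                 nt_error_rate: float = 0.0,
                 ) -> tuple[list[SequenceRecord], pd.DataFrame, pd.DataFrame]:
    """Planted dataset: records, annotation table, and truth table.

    Planted (secreted) proteins are annotated with HMM signal-peptide
    probability 0.95; decoys get 0.1 and all-'N' neural-network flags.
    When ``outdir`` is given, writes ``proteins.fasta`` (and
    ``ests.fasta`` when ``as_nucleotide``), ``annotations.tsv`` and
    ``truth.tsv``.
    """
    if not specs:
        raise ValueError("at least one family spec required")
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for spec in specs:
        for j in range(spec.members):
            rec, truth = make_tr_protein(spec, j)
            records.append(rec)
            truths.append(truth)
    for j in range(decoys):
        records.append(make_decoy(seed, j))
    ann_rows = []
    truth_ids = {t.id: t for t in truths}
    for rec in records:
        secreted = rec.id in truth_ids and truth_ids[rec.id].secreted
        ann_rows.append({
            "id": rec.id,
            "hmm_sp_probability": 0.95 if secreted else 0.10,
            "nn_max_C": "Y" if secreted else "N",
            "nn_max_Y": "Y" if secreted else "N",
            "nn_max_S": "Y" if secreted else "N",
            "nn_mean_S": "Y" if secreted else "N",
            "nn_D": "Y" if secreted else "N",
            "gpi_specificity": "",
        })
    annotations = pd.DataFrame(ann_rows)
    truth_df = pd.DataFrame([vars(t) for t in truths])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .seqio import write_fasta

        write_fasta(records, outdir / "proteins.fasta")
        if as_nucleotide:
            rng = np.random.default_rng([seed & 0x7FFFFFFF, 99])
            with open(outdir / "ests.fasta", "w") as fh:
                for r in records:
                    nt = reverse_translate(r.sequence, rng,
                                           error_rate=nt_error_rate)
                    fh.write(f">{r.id}\n")
                    for k in range(0, len(nt), 60):
                        fh.write(nt[k:k + 60] + "\n")
        annotations.to_csv(outdir / "annotations.tsv", sep="\t",
                           index=False)
        truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return records, annotations, truth_df
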