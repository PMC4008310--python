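"""Standard genetic code keyed by RNA codons, with synonymous-family structure.

Every index in this package (RSCU, ENC, CAI, GC3s) is defined relative to
synonymous codon families, so the code object precomputes the family of each
codon, the degeneracy classes (family sizes 2, 3, 4 and 6 among the amino
acids; Met and Trp are singletons), and the 59-codon set used for
comparative RSCU analyses (64 minus AUG, UGG and the three stops).
"""

from __future__ import annotations

from Bio.Data import CodonTable as _CodonTable

BASES = ("A", "C", "G", "U")
START_CODON = "AUG"
STOP_CODONS = ("UAA", "UAG", "UGA")
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


class GeneticCode:
    """The standard code by default; any NCBI translation table id works.

    Attributes
    ----------
    codon_to_aa : dict
        64 RNA codons -> one-letter amino acid, stops mapped to ``"*"``.
    families : dict
        amino acid (incl. ``"*"``) -> tuple of synonymous codons, sorted.
    degeneracy_classes : dict
        family size k in {2, 3, 4, 6} -> tuple of amino acids (stops and
        singleton families excluded); this is the structure Wright's ENC
        averages over.
    sense_codons : tuple
        the 61 non-stop codons.
    synonymous_codons : tuple
        the 59 codons belonging to families of size >= 2 (no stops).
    """

    def __init__(self, table_id: int = 1):
        bio = _CodonTable.unambiguous_rna_by_id[table_id]
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = dict(bio.forward_table)
        for stop in bio.stop_codons:
            self.codon_to_aa[stop] = "*"
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"translation table {table_id} does not cover 64 codons")
        self.stop_codons = tuple(sorted(bio.stop_codons))

        fams: dict[str, list[str]] = {}
        for codon in sorted(self.codon_to_aa):
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(cods) for aa, cods in sorted(fams.items())
        }
        self.family_of: dict[str, tuple[str, ...]] = {
            codon: self.families[aa] for codon, aa in self.codon_to_aa.items()
        }
        self.single_codon_aas = tuple(
            aa for aa, fam in self.families.items() if aa != "*" and len(fam) == 1
        )

        classes: dict[int, list[str]] = {}
        for aa, fam in self.families.items():
            if aa == "*" or len(fam) < 2:
                continue
            classes.setdefault(len(fam), []).append(aa)
        self.degeneracy_classes: dict[int, tuple[str, ...]] = {
            k: tuple(sorted(aas)) for k, aas in sorted(classes.items())
        }

        self.sense_codons = tuple(
            c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] != "*"
        )
        singleton_codons = {
            self.families[aa][0] for aa in self.single_codon_aas
        }
        self.synonymous_codons = tuple(
            c for c in self.sense_codons if c not in singleton_codons
        )

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticCode(table_id={self.table_id})"


#: Shared default instance (the standard code).
STANDARD_CODE = GeneticCode()
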