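"""Published reference data for the CPD cephalopod marker system.

The CPD primer set amplifies a 465-471 bp region spanning mitochondrial
cytochrome b into ND6 (including their intergenic spacer, a peculiarity of
cephalopod mitogenome architecture).  The forward primer carries five
degenerate wobble positions and the reverse four, with the conserved second
codon placed at each 3' terminus.

This module records, as plain data:

* the CPD primer pair and its Nextera-adapter-extended library variants;
* the forward-primer binding-site variants observed across the 36 complete
  cephalopod mitogenomes the primers were designed from (one 17-mer per
  species, indexed by GenBank accession);
* the published monthly contig counts from the 2016 Korean-waters
  planktonic cephalopod survey, used as a worked example for proportion
  arithmetic.
"""

from __future__ import annotations

from .iupac import DegenerateSequence

CPD_FWD = "GAYATYTGNCCYCADGG"
CPD_RVS = "ATTTGYTAYTAYTGTGANGG"

#: Nextera XT adapter prefixes used on the library-prep (NXT) primer variants.
NEXTERA_FWD_ADAPTER = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"  # 33 nt
NEXTERA_RVS_ADAPTER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"  # 34 nt

NXT_CPD_FWD = NEXTERA_FWD_ADAPTER + CPD_FWD
NXT_CPD_RVS = NEXTERA_RVS_ADAPTER + CPD_RVS


def cpd_primer_pair():
    """The CPD primer pair as :class:`~cpdtools.primers.PrimerPair`."""
    from .primers import PrimerPair

    return PrimerPair(
        fwd=DegenerateSequence(CPD_FWD),
        rvs=DegenerateSequence(CPD_RVS),
        name="CPD",
    )


# Forward-primer site across the 36 reference mitogenomes.  The consensus is
# CPD_FWD; the five wobble (codon third) positions 3, 6, 9, 12 and 15
# (1-based) vary per species and are listed here in that order.
# (family, species, accession, bases at the five wobble positions)
CPD_FWD_SITE_VARIANTS: list[tuple[str, str, str, str]] = [
    ("Sepiidae", "Sepia pharaonis", "AP013076", "TCACA"),
    ("Sepiidae", "Sepia lycidas", "AP013075", "TTATA"),
    ("Sepiidae", "Sepia apama", "AP013073", "TTACA"),
    ("Sepiidae", "Sepia esculenta", "AB266516", "TTATA"),
    ("Sepiidae", "Sepia latimanus", "AP013074", "TTATA"),
    ("Sepiidae", "Sepia officinalis", "AB240155", "TCATT"),
    ("Sepiidae", "Sepiella inermis", "NC022693", "TTATA"),
    ("Sepiidae", "Sepiella maindroni", "KR912215", "TTATA"),
    ("Sepiidae", "Sepiella japonica", "AB675082", "TTATA"),
    ("Sepiolidae", "Semirossia patagonica", "AP013073", "TTCTA"),
    ("Loliginidae", "Heterololigo bleekeri", "AB029616", "TTCTA"),
    ("Loliginidae", "Uroteuthis edulis", "AB675081", "TTATA"),
    ("Loliginidae", "Uroteuthis duvaucelii", "KR051264", "CCTTA"),
    ("Loliginidae", "Uroteuthis chinensis", "NC028189", "TTACA"),
    ("Loliginidae", "Loliolus uyii", "KP265013", "CTATA"),
    ("Loliginidae", "Loliolus beka", "NC028034", "CCACA"),
    ("Loliginidae", "Loliolus japonica", "NC030208", "CCATA"),
    ("Loliginidae", "Sepioteuthis lessoniana", "AB240154", "TTATA"),
    ("Loliginidae", "Doryteuthis opalescens", "KP336703", "CCCTG"),
    ("Enoploteuthidae", "Watasenia scintillans", "AB240152", "TTGTA"),
    ("Ommastrephidae", "Ommastrephes bartramii", "AB715401", "CTACA"),
    ("Ommastrephidae", "Todarodes pacificus", "AB240153", "CTATA"),
    ("Ommastrephidae", "Illex argentinus", "NC026908", "TTATA"),
    ("Ommastrephidae", "Dosidicus gigas", "EU068697", "CTATA"),
    ("Ommastrephidae", "Sthenoteuthis oualaniensis", "NC010636", "TTCCA"),
    ("Bathyteuthidae", "Bathyteuthis abyssicola", "AP012225", "CCATA"),
    ("Idiosepiidae", "Idiosepius sp.", "KF647895", "TTATA"),
    ("Octopodidae", "Octopus minor", "HQ638215", "TTATT"),
    ("Octopodidae", "Octopus vulgaris", "AB158363", "TCATA"),
    ("Octopodidae", "Octopus conispadiceus", "NC029747", "TTACA"),
    ("Octopodidae", "Octopus bimaculatus", "NC028547", "TTATA"),
    ("Octopodidae", "Octopus bimaculoides", "KU295559", "TTATA"),
    ("Octopodidae", "Amphioctopus fangsiao", "AB240156", "TTTTA"),
    ("Octopodidae", "Amphioctopus aegina", "NC029702", "TTTTA"),
    ("Octopodidae", "Amphioctopus marginatus", "KY646153", "TTACA"),
    ("Vampyroteuthidae", "Vampyroteuthis infernalis", "AB266515", "TTTTA"),
]

#: 0-based indices of the wobble positions within the 17-nt forward site.
CPD_FWD_WOBBLE_INDICES = (2, 5, 8, 11, 14)


def cpd_fwd_site_sequences() -> list[str]:
    """Concrete 17-nt forward-primer site per reference mitogenome.

    Reconstructed by substituting each species' observed wobble bases into
    the consensus; the position-wise IUPAC collapse of the returned list is
    the CPD forward primer itself.
    """
    sites = []
    for _family, _species, _acc, wobble in CPD_FWD_SITE_VARIANTS:
        site = list(CPD_FWD)
        for idx, base in zip(CPD_FWD_WOBBLE_INDICES, wobble):
            site[idx] = base
        sites.append("".join(site))
    return sites


# Monthly contig counts per assigned taxon from the 2016 Korean-waters
# survey (February-May shown in the published summary table with non-empty
# cells only).  Used to exercise proportion-table arithmetic and formatting.
KOREAN_SURVEY_2016_COUNTS: dict[str, dict[str, int]] = {
    "February": {
        "Watasenia scintillans": 107_830,
        "Todarodes pacificus": 2_286,
        "Sepiola birostrata": 74,
        "Dosidicus sp.": 15,
    },
    "March": {
        "Watasenia scintillans": 61_514,
        "Todarodes pacificus": 45_805,
        "Sepiola birostrata": 2_676,
    },
    "April": {
        "Watasenia scintillans": 85_853,
        "Sepiola birostrata": 14,
        "Unidentified Oegopsida 2": 6,
    },
    "May": {
        "Watasenia scintillans": 206_811,
        "Todarodes sp.": 3,
        "Unidentified Oegopsida 1": 50,
        "Unidentified Oegopsida 2": 43,
    },
}

#: Distinct haplotype counts behind each cell of the survey table (all 1).
KOREAN_SURVEY_2016_HAPLOTYPES: dict[str, dict[str, int]] = {
    month: {taxon: 1 for taxon in counts}
    for month, counts in KOREAN_SURVEY_2016_COUNTS.items()
}
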