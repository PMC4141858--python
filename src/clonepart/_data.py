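"""Published worldwide Melanaphis sacchari reference data, embedded as CSV text.

Two small machine-readable tables ship with the package:

* ``TABLE1_CSV`` — the 36 observed microsatellite multilocus genotypes (MLGs)
  at 10 CIR-Ms loci, with the multilocus-lineage (MLL) label each MLG was
  assigned to (lineages A-E).  Allele sizes are fragment lengths in bp.
* ``TABLE2_CSV`` — the distribution of the 98 retained representatives (one
  per MLG per sample) over country/province, host plant and MLL, with the
  number of field samples each row derives from.

The source tables use "//" in a couple of cells as a typographic variant of
the "/" allele separator; that is normalised here.  Bold highlighting of
within-lineage variable alleles in the original has no data content and is
not represented.
"""

TABLE1_LOCI = [
    "CIR-Ms-G08",
    "CIR-Ms-G403",
    "CIR-Ms-B03",
    "CIR-Ms-C08",
    "CIR-Ms-G01",
    "CIR-Ms-E01",
    "CIR-Ms-G12",
    "CIR-Ms-E03",
    "CIR-Ms-D02",
    "CIR-Ms-G02",
]

TABLE1_CSV = """\
mll,mlg,CIR-Ms-G08,CIR-Ms-G403,CIR-Ms-B03,CIR-Ms-C08,CIR-Ms-G01,CIR-Ms-E01,CIR-Ms-G12,CIR-Ms-E03,CIR-Ms-D02,CIR-Ms-G02
A,Ms5,229/229,253/253,215/215,189/203,206/210,245/247,214/216,176/176,220/228,250/316
A,Ms30,229/229,253/253,215/215,189/203,204/206,245/247,214/216,176/176,220/228,250/318
A,Ms31,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,228/230,254/314
A,Ms41,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/226,252/314
A,Ms42,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/226,254/314
A,Ms301,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,248/312
A,Ms302,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,248/314
A,Ms303,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/298
A,Ms304,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/310
A,Ms305,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/312
A,Ms306,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/314
A,Ms307,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/316
A,Ms308,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/318
A,Ms309,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/343
A,Ms310,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,250/345
A,Ms311,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,252/312
A,Ms312,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,252/314
A,Ms313,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,254/312
A,Ms314,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,254/314
A,Ms315,229/229,253/253,215/215,189/203,206/206,245/247,214/216,176/176,220/228,256/314
B,Ms1,233/233,253/259,213/215,197/199,185/206,247/247,212/216,188/193,226/232,199/199
B,Ms2,233/233,253/259,213/215,197/199,185/206,247/247,212/216,188/193,226/252,199/199
B,Ms121,233/233,253/259,213/215,197/199,185/206,247/247,212/216,188/191,226/232,199/199
B,Ms122,233/233,253/259,213/215,197/199,185/206,247/247,212/216,188/191,226/232,199/201
C,Ms6,233/233,251/259,213/213,197/199,185/210,247/247,212/216,186/193,228/234,199/199
C,Ms7,233/233,251/259,213/213,197/199,185/210,247/247,204/212,186/193,228/232,199/199
C,Ms8,233/233,251/259,213/213,197/199,185/212,247/247,212/216,186/193,228/232,199/199
C,Ms11,233/233,251/259,213/213,197/199,185/210,247/247,212/216,186/193,228/232,199/199
C,Ms12,233/233,251/259,213/213,195/197,185/210,247/247,212/216,186/193,228/232,199/205
C,Ms15,233/233,251/259,213/213,197/199,185/210,247/247,212/216,186/193,228/232,199/201
C,Ms16,233/233,251/259,213/213,195/197,185/210,247/247,212/216,186/193,228/232,199/203
C,Ms21,233/233,251/259,213/213,195/197,185/210,247/247,212/216,186/193,228/234,199/203
D,Ms9,233/233,251/259,213/213,197/199,185/206,247/247,212/216,186/188,226/234,201/201
D,Ms10,233/233,251/259,213/213,197/199,185/206,247/247,212/218,186/188,226/234,201/201
E,Ms32,229/229,253/253,215/215,197/197,198/206,245/245,208/212,216/224,220/222,216/216
E,Ms33,229/229,253/253,215/215,197/197,198/206,245/245,208/212,224/224,220/222,216/216
"""

# Retained representatives per (state, host, MLL).
TABLE2_CSV = """\
state,host,mll,n_individuals
Benin,sorghum,A,3
Benin,sugarcane,A,6
Benin,pearl millet,A,1
Cameroon,sorghum,A,20
Kenya,sorghum,A,2
Kenya,sugarcane,A,2
Kenya,sugarcane,C,4
Niger,sorghum,A,5
Australia,sugarcane,B,11
Brazil,sugarcane,C,2
Columbia,sugarcane,C,7
Ecuador,sugarcane,C,1
Guadeloupe,sugarcane,C,6
Martinique,sugarcane,C,3
Mauritius,sugarcane,C,1
Reunion,sorghum,C,3
Reunion,sugarcane,C,7
Hawaii,sugarcane,D,3
Louisiana,sorghum,D,1
Louisiana,sugarcane,D,8
China,sorghum,E,2
"""

# Field samples per (state, host); a sample = one host plant species in one
# locality on one date.
TABLE2_SAMPLES_CSV = """\
state,host,n_samples
Benin,sorghum,2
Benin,sugarcane,1
Benin,pearl millet,1
Cameroon,sorghum,5
Kenya,sorghum,1
Kenya,sugarcane,4
Niger,sorghum,2
Australia,sugarcane,7
Brazil,sugarcane,1
Columbia,sugarcane,3
Ecuador,sugarcane,1
Guadeloupe,sugarcane,5
Martinique,sugarcane,3
Mauritius,sugarcane,1
Reunion,sorghum,3
Reunion,sugarcane,5
Hawaii,sugarcane,3
Louisiana,sorghum,1
Louisiana,sugarcane,7
China,sorghum,1
"""
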