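seed: 0
n_countries: 24
sites_per_country_per_bin:
  PLEISTOCENE: 10
  HOLOCENE: 10
  B1500_1959: 10
  B1960_1969: 10
  B1970_1979: 10
  B1980_1984: 20
  B1985_1989: 20
  B1990_1994: 20
  B1995_2000: 20
  B2001_2004: 20
  B2005_2011: 20
sigma_u: 0.5
zone: crest
site_sd_by_bin:
  PLEISTOCENE: 1.1
  HOLOCENE: 1.1
  B1500_1959: 1.1
  B1960_1969: 0.95
  B1970_1979: 0.8
  B1980_1984: 0.65
  B1985_1989: 0.55
  B1990_1994: 0.45
  B1995_2000: 0.4
  B2001_2004: 0.35
  B2005_2011: 0.35
time_averaging_factor: 0.5
missingness_rate: 0.05
trajectories:
  ACER:
    PLEISTOCENE: 0.75
    HOLOCENE: 0.73
    B1500_1959: 0.72
    B1960_1969: 0.35
    B1970_1979: 0.25
    B1980_1984: 0.2
    B1985_1989: 0.17
    B1990_1994: 0.14
    B1995_2000: 0.12
    B2001_2004: 0.1
    B2005_2011: 0.09
  APAL:
    PLEISTOCENE: 0.88
    HOLOCENE: 0.87
    B1500_1959: 0.85
    B1960_1969: 0.5
    B1970_1979: 0.38
    B1980_1984: 0.3
    B1985_1989: 0.27
    B1990_1994: 0.25
    B1995_2000: 0.25
    B2001_2004: 0.24
    B2005_2011: 0.24
  AGARICIA:
    PLEISTOCENE: 0.18
    HOLOCENE: 0.19
    B1500_1959: 0.2
    B1960_1969: 0.28
    B1970_1979: 0.42
    B1980_1984: 0.56
    B1985_1989: 0.7
    B1990_1994: 0.68
    B1995_2000: 0.66
    B2001_2004: 0.64
    B2005_2011: 0.64
  MCAV:
    PLEISTOCENE: 0.28
    HOLOCENE: 0.28
    B1500_1959: 0.28
    B1960_1969: 0.3
    B1970_1979: 0.37
    B1980_1984: 0.46
    B1985_1989: 0.55
    B1990_1994: 0.58
    B1995_2000: 0.56
    B2001_2004: 0.54
    B2005_2011: 0.53
  COLPOPHYLLIA:
    PLEISTOCENE: 0.18
    HOLOCENE: 0.18
    B1500_1959: 0.18
    B1960_1969: 0.2
    B1970_1979: 0.25
    B1980_1984: 0.32
    B1985_1989: 0.4
    B1990_1994: 0.42
    B1995_2000: 0.38
    B2001_2004: 0.34
    B2005_2011: 0.3
  PSEUDODIPLORIA:
    PLEISTOCENE: 0.65
    HOLOCENE: 0.64
    B1500_1959: 0.62
    B1960_1969: 0.6
    B1970_1979: 0.62
    B1980_1984: 0.64
    B1985_1989: 0.68
    B1990_1994: 0.65
    B1995_2000: 0.63
    B2001_2004: 0.62
    B2005_2011: 0.62
  MADRACIS:
    PLEISTOCENE: 0.03
    HOLOCENE: 0.03
    B1500_1959: 0.03
    B1960_1969: 0.05
    B1970_1979: 0.09
    B1980_1984: 0.15
    B1985_1989: 0.22
    B1990_1994: 0.24
    B1995_2000: 0.23
    B2001_2004: 0.22
    B2005_2011: 0.22
  MEANDRINA:
    PLEISTOCENE: 0.08
    HOLOCENE: 0.08
    B1500_1959: 0.08
    B1960_1969: 0.09
    B1970_1979: 0.12
    B1980_1984: 0.18
    B1985_1989: 0.24
    B1990_1994: 0.26
    B1995_2000: 0.24
    B2001_2004: 0.22
    B2005_2011: 0.21
  MILLEPORA:
    PLEISTOCENE: 0.08
    HOLOCENE: 0.09
    B1500_1959: 0.1
    B1960_1969: 0.18
    B1970_1979: 0.3
    B1980_1984: 0.45
    B1985_1989: 0.6
    B1990_1994: 0.75
    B1995_2000: 0.84
    B2001_2004: 0.87
    B2005_2011: 0.88
  ORBICELLA:
    PLEISTOCENE: 0.72
    HOLOCENE: 0.71
    B1500_1959: 0.7
    B1960_1969: 0.69
    B1970_1979: 0.69
    B1980_1984: 0.68
    B1985_1989: 0.68
    B1990_1994: 0.67
    B1995_2000: 0.68
    B2001_2004: 0.69
    B2005_2011: 0.7
  PORITES_BRANCHING:
    PLEISTOCENE: 0.33
    HOLOCENE: 0.34
    B1500_1959: 0.35
    B1960_1969: 0.42
    B1970_1979: 0.55
    B1980_1984: 0.66
    B1985_1989: 0.75
    B1990_1994: 0.74
    B1995_2000: 0.73
    B2001_2004: 0.73
    B2005_2011: 0.73
  PASTREOIDES:
    PLEISTOCENE: 0.17
    HOLOCENE: 0.18
    B1500_1959: 0.2
    B1960_1969: 0.35
    B1970_1979: 0.52
    B1980_1984: 0.67
    B1985_1989: 0.83
    B1990_1994: 0.82
    B1995_2000: 0.82
    B2001_2004: 0.82
    B2005_2011: 0.82
  SIDERASTREA:
    PLEISTOCENE: 0.15
    HOLOCENE: 0.16
    B1500_1959: 0.18
    B1960_1969: 0.25
    B1970_1979: 0.42
    B1980_1984: 0.62
    B1985_1989: 0.8
    B1990_1994: 0.79
    B1995_2000: 0.78
    B2001_2004: 0.77
    B2005_2011: 0.77
  STEPHANOCOENIA:
    PLEISTOCENE: 0.02
    HOLOCENE: 0.02
    B1500_1959: 0.03
    B1960_1969: 0.06
    B1970_1979: 0.14
    B1980_1984: 0.26
    B1985_1989: 0.38
    B1990_1994: 0.4
    B1995_2000: 0.38
    B2001_2004: 0.37
    B2005_2011: 0.36
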