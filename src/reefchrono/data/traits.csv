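species_group,life_history_group,morphology,growth_rate_mm_yr,growth_label,reproductive_mode,reproductive_output,asexual_propagation,aggression,bleaching_susceptibility,sediment_tolerance
ACER,competitive,large_branching,119.5,fast,spawner,low,high,moderate,high,low
APAL,competitive,large_branching,68.4,fast,spawner,low,high,moderate,high,low
MILLEPORA,competitive,plating_branching,13.2,fast,spawner,moderate,high,high,high,high
COLPOPHYLLIA,stress_tolerant,domed,7.0,moderate,spawner,low,low,high,moderate_low,high
PSEUDODIPLORIA,stress_tolerant,domed,5.7,moderate,spawner,low,low,moderate,low,high
MEANDRINA,stress_tolerant,domed,1.1,slow,spawner,low,low,moderate,moderate,high
MCAV,stress_tolerant,domed,5.8,moderate,spawner,low,low,moderate,low,high
ORBICELLA,stress_tolerant,domed,7.9,moderate,spawner,low,moderate_low,high,high,moderate_high
SIDERASTREA,stress_tolerant,domed,3.7,slow,mixed,low_moderate,low,low,moderate_high,high
STEPHANOCOENIA,stress_tolerant,domed,5.0,moderate,spawner,low_moderate,low,low,high,high
AGARICIA,weedy,plating_foliose,1.6,slow,brooder,high,low,low,high,moderate
PORITES_BRANCHING,weedy,small_branching,16.0,fast,brooder,high,high,low,moderate_high,high
PASTREOIDES,weedy,domed,4.0,slow,brooder,high,low,low,high,high
MADRACIS,weedy,small_branching,6.3,moderate,brooder,moderate,high,low,low,high
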