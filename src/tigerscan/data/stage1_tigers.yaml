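# Stage-1 continent-island demography for the four tiger subspecies:
# Sumatran (SUM), Bengal (BEN), Malayan (MAL) and Amur (AMU) diverge from a
# large Asian metapopulation within the Holocene (1,500-1,840 generations
# at 5 years per generation) while receiving weak continued immigration
# (fewer than one migrant lineage per generation).  SUM and BEN carry a
# founder effect at their divergence; SUM and AMU carry strong recent
# bottlenecks; the metapopulation itself passed through an ancient
# bottleneck (~234 kya / 46,800 generations, the species' founding event).
# Sizes are a desk-scale configuration consistent with the observed
# diversity ranking (BEN highest, SUM lowest) and are not published
# estimates.
mutation_rate: 0.35e-8
generation_time: 5.0
recombination_rate: 0.0
metapopulations:
  - name: Asia
    diploid_size: 30000
populations:
  - name: SUM
    diploid_size: 2500
    sample_size: 3
    divergence_time: 1840
    migration_rate: 5.0e-05
  - name: BEN
    diploid_size: 15000
    sample_size: 3
    divergence_time: 1680
    migration_rate: 5.0e-05
  - name: MAL
    diploid_size: 6000
    sample_size: 4
    divergence_time: 1500
    migration_rate: 5.0e-05
  - name: AMU
    diploid_size: 3500
    sample_size: 3
    divergence_time: 1500
    migration_rate: 5.0e-05
bottlenecks:
  - population: SUM
    start_time: 1790
    duration: 50
    bottleneck_size: 100
  - population: BEN
    start_time: 1630
    duration: 50
    bottleneck_size: 300
  - population: SUM
    start_time: 10
    duration: 10
    bottleneck_size: 50
  - population: AMU
    start_time: 10
    duration: 10
    bottleneck_size: 60
  - population: BEN
    start_time: 10
    duration: 10
    bottleneck_size: 500
  - population: MAL
    start_time: 10
    duration: 10
    bottleneck_size: 500
  - population: Asia
    start_time: 46800
    duration: 200
    bottleneck_size: 1000
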