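# Year-by-year stage tables for the shipped breeding calendars.
#
# Keys are cohort ages in years since crossing (age 0 is the crossing
# year itself); each entry is an ordered list of steps executed in that
# year.  Steps: {ssd: g} advances every line g selfing generations;
# mas / lst apply within-family phenotypic selection at row
# heritability; oyt applies across-family phenotypic selection at plot
# heritability (single location); seed_amp only consumes calendar time;
# stage1 runs the recycling-point yield trial and scoring; est
# phenotypes a training sample and pushes it into the rolling training
# population (between-cohort prediction only); stage2 runs the advanced
# yield trial on the lines already picked at stage1.
#
# criterion: phenotype        selection scores are trial phenotypes
#            within_cohort    RR-BLUP trained on this cohort's EST
#            between_cohort   RR-BLUP trained on the rolling window of
#                             earlier cohorts' EST data
baseline:
  recycle_age: 4
  criterion: phenotype
  stages:
    1: [{ssd: 5}]
    2: [{mas: null}]
    3: [{seed_amp: null}]
    4: [{stage1: null}]
    5: [{stage2: null}]
5-year:
  recycle_age: 4
  criterion: within_cohort
  stages:
    1: [{ssd: 5}]
    2: [{mas: null}]
    3: [{seed_amp: null}]
    4: [{stage1: null}]
    5: [{stage2: null}]
3-year:
  recycle_age: 2
  criterion: within_cohort
  stages:
    1: [{ssd: 3}, {mas: null}, {ssd: 1}]
    2: [{stage1: null}]
    3: [{stage2: null}]
2-year-wp:
  recycle_age: 1
  criterion: within_cohort
  stages:
    1: [{ssd: 2}, {mas: null}, {ssd: 1}, {stage1: null}]
    2: [{stage2: null}]
2-year-bp:
  recycle_age: 1
  criterion: between_cohort
  stages:
    1: [{ssd: 3}, {mas: null}, {ssd: 1}, {stage1: null}]
    2: [{est: null}]
    3: [{stage2: null}]
burnin:
  recycle_age: 4
  criterion: phenotype
  stages:
    1: [{ssd: 5}]
    2: [{lst: null}]
    3: [{oyt: null}]
    4: [{stage1: null}]
    5: [{stage2: null}]
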