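# Default genomic comparison set: each flag's carriers vs tumor samples
# without the flag.  Control membership is an assumption of this package
# (the original case/control rosters are not public); edit freely.
comparisons:
  - name: t_4_14
    case: {all: [t_4_14]}
    control: {none: [t_4_14]}
  - name: t_11_14
    case: {all: [t_11_14]}
    control: {none: [t_11_14]}
  - name: t_14_16
    case: {all: [t_14_16]}
    control: {none: [t_14_16]}
  - name: t_6_14
    case: {all: [t_6_14]}
    control: {none: [t_6_14]}
  - name: t_14_20
    case: {all: [t_14_20]}
    control: {none: [t_14_20]}
  - name: hyperdiploid
    case: {all: [hyperdiploid]}
    control: {none: [hyperdiploid]}
  - name: gain1q
    case: {all: [gain1q]}
    control: {none: [gain1q]}
  - name: amp1q
    case: {all: [amp1q]}
    control: {none: [amp1q]}
  - name: del17p
    case: {all: [del17p]}
    control: {none: [del17p]}
  - name: del13q
    case: {all: [del13q]}
    control: {none: [del13q]}
  - name: mut_DIS3
    case: {all: [mut_DIS3]}
    control: {none: [mut_DIS3]}
  - name: mut_TENT5C
    case: {all: [mut_TENT5C]}
    control: {none: [mut_TENT5C]}
  - name: mut_TP53
    case: {all: [mut_TP53]}
    control: {none: [mut_TP53]}
  - name: mut_SF3B1
    case: {all: [mut_SF3B1]}
    control: {none: [mut_SF3B1]}
  - name: mut_SF3B1_hotspot
    case: {all: [mut_SF3B1_hotspot]}
    control: {none: [mut_SF3B1_hotspot]}
  - name: biallelic_DIS3
    case: {all: [biallelic_DIS3]}
    control: {none: [biallelic_DIS3]}
  - name: biallelic_TENT5C
    case: {all: [biallelic_TENT5C]}
    control: {none: [biallelic_TENT5C]}
  - name: biallelic_TP53
    case: {all: [biallelic_TP53]}
    control: {none: [biallelic_TP53]}
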