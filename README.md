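# biomemory

An in silico simulator of a DNA-based associative memory for genomic
pattern classification: a wet-lab protocol that *learns* the sequence
content of a genomic sample without knowing its sequence, and *recalls*
it later by hybridization against new samples.

## The problem and the protocol

Most sequence-based diagnostics require prior knowledge — primers or
probes for known targets. The protocol simulated here instead captures
a snapshot of **all** DNA in a sample. A *memory tag* is a 40-nt oligo:
a fixed 20-base non-crosshybridizing (NCH) address tag with a 5'
biotin/amine modification, followed by a 20-base random probe (R20).
Because the R20 library spans 4^20 ≈ 1.1 × 10^12 sequences — with
multiple copies of each present in a 50 μL reaction at 1.6 μM — probes
anneal at random stable sites across any genome. Learning is
A → E → D: **A**nnealing of tags to denatured ~200-base fragments,
Klenow **E**xtension (trim the primer's unpaired 3' tail, copy the
template to its 5' end), and Exo I **D**igestion of unbound strands,
followed by bead separation of the 5'-modified products. The retained
single strands — tag plus complement of genomic sequence — are a
content-addressable memory. Recall prints learned pools as microarray
spots and hybridizes labeled fragments of a new sample against them;
similarity appears as spot signal (background-subtracted intensity,
detection at SNR > 3).

The package simulates every stage — nearest-neighbor duplex
thermodynamics with Mg²⁺/dNTP salt corrections (SantaLucia-1998 table,
Owczarzy correction, excess-oligo strand term), synthetic genomes and
DNase-I fragmentation, the annealing/extension/digestion/separation
pipeline, tag-tag by-product accounting, and array printing,
labeling, hybridization, and SNR-based detection — plus k-mer
commonality analytics for judging whether two genomes are
discriminable. See `docs/methods.md` for the model in full.

## Worked example

Duplex stability under the learning reaction condition (1.6 μM oligo,
10 mM Na⁺, 10 mM Mg²⁺, 4 mM dNTPs):

```
$ biomemory thermo kstats --k 5 --k 7 --mode exhaustive
k,min_tm,mean_tm,max_tm,method,param_set
5,-33.048...,-0.485...,31.301...,exhaustive,santalucia-unified-1998
7,-4.227...,25.845...,53.942...,exhaustive,santalucia-unified-1998

$ biomemory thermo anchor --temperature 25 --stat mean
7
```

The strongest 5-mer melts at ~31 °C and the *average* 7-mer at ~26 °C,
so at the 25 °C annealing temperature a typical duplex needs about 7
bases — short partial pairings are stable, which is why tag-tag
by-products form at low temperature and why the protocol anneals at
55 °C instead.

The reaction-order experiment (one 100-kb synthetic genome, 10³ tags,
25 °C annealing) shows why digestion must come last:

```
$ biomemory experiment order --seed 7
{
  ...
  "lp_h_aed": 743,
  "lp_h_ade": 0,
  "order_effect_confirmed": true
}
```

A → E → D yields 743 high-molecular-weight (>80 nt) learned products;
A → D → E yields none, because Exo I destroys the annealed-but-
unextended complexes before the polymerase can lock them in.

The nine-point titration learns mixtures of strain A in a strain-B
background and recalls them with pure-A probes
(`biomemory experiment titration --seed 1`): the 0% spot stays below
the SNR 3 detection threshold, 10% is detected, and mean spot intensity
rises monotonically with the target fraction (see
`results/acceptance.json` after running the script below).

K-mer commonality between two genome FASTA files (the premise for
discriminating strains by hybridization):

```
$ biomemory kmer common strainA.fasta strainB.fasta --k 14
```

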