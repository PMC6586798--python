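# Packaged substrate library and enzyme definitions.
#
# Substrates mirror the assay's oligonucleotide toolkit: an 80-bp duplex core
# with biotin-TEG+streptavidin end blocks (blocked_ends), 3'/5' overhang
# variants, nick/gap variants, mismatch and methylcytosine variants, ssDNA
# 20/40/60/80-mers, primer-template hybrids for polymerase mode, and ssRNA /
# RNA:DNA-hybrid substrates for the RNA dye.  Coordinates are 0-based nt.
# Naming: a trailing "_b3" / "_b5" marks the blocked end(s); "ovh" entries are
# overhang lengths on the free attacking end.
#
# Enzyme rates: "rate" is the observed bulk per-nM maximum-gradient rate on
# the reference substrate; "rate_basis" says how the simulator's intrinsic
# per-front rate is derived from it (see library.py):
#   bulk_one_blocked — reference substrate has one blocked end; intrinsic
#                      per-front rate = rate / (2 - purity)
#   per_front        — rate is already the per-front rate
#   per_nt_hazard    — distributive mode: per-nt hazard = rate / ref_length
#   nicking          — motif map carries per-site nicking rates (s^-1 nM^-1)

substrates:
  # --- duplex core and end-block variants -------------------------------
  - {name: S_blunt, duplex_length: 80}
  - {name: S_b3, duplex_length: 80, blocked_ends: [top3]}
  - {name: S_b3b3, duplex_length: 80, blocked_ends: [top3, bot3]}
  - {name: S_b5, duplex_length: 80, blocked_ends: [bot5]}
  - {name: S_b5b5, duplex_length: 80, blocked_ends: [top5, bot5]}
  # --- 3' overhangs on the free 3' end (ExoIII series) ------------------
  - {name: S_b3_ovh2, duplex_length: 80, blocked_ends: [top3], bottom_3p_overhang: 2}
  - {name: S_b3_ovh4, duplex_length: 80, blocked_ends: [top3], bottom_3p_overhang: 4}
  # --- 5' overhangs on the free 5' end (T7 Exo series) ------------------
  - {name: S_b5_ovh2, duplex_length: 80, blocked_ends: [bot5], top_5p_overhang: 2}
  - {name: S_b5_ovh10, duplex_length: 80, blocked_ends: [bot5], top_5p_overhang: 10}
  - {name: S_b5_ovh20, duplex_length: 80, blocked_ends: [bot5], top_5p_overhang: 20}
  # --- mismatch variants (four lesions spanning the 80-nt tract) --------
  - name: S_b3_mmAC
    duplex_length: 80
    blocked_ends: [top3]
    lesions:
      - {strand: both, position: 10, kind: mismatch_AC, rate_multiplier: 1.65, window_nt: 20}
      - {strand: both, position: 30, kind: mismatch_AC, rate_multiplier: 1.65, window_nt: 20}
      - {strand: both, position: 50, kind: mismatch_AC, rate_multiplier: 1.65, window_nt: 20}
      - {strand: both, position: 70, kind: mismatch_AC, rate_multiplier: 1.65, window_nt: 20}
  - name: S_b3_mmTG
    duplex_length: 80
    blocked_ends: [top3]
    lesions:
      - {strand: both, position: 10, kind: mismatch_TG, rate_multiplier: 0.125, window_nt: 20}
      - {strand: both, position: 30, kind: mismatch_TG, rate_multiplier: 0.125, window_nt: 20}
      - {strand: both, position: 50, kind: mismatch_TG, rate_multiplier: 0.125, window_nt: 20}
      - {strand: both, position: 70, kind: mismatch_TG, rate_multiplier: 0.125, window_nt: 20}
  # --- methylcytosine variants (initiation delay, rate unchanged) -------
  - name: S_b3_1M
    duplex_length: 80
    blocked_ends: [top3]
    lesions:
      - {strand: bottom, position: 40, kind: methyl_C, initiation_delay_s: 150}
  - name: S_b3_4M
    duplex_length: 80
    blocked_ends: [top3]
    lesions:
      - {strand: bottom, position: 10, kind: methyl_C, initiation_delay_s: 150}
      - {strand: bottom, position: 30, kind: methyl_C, initiation_delay_s: 150}
      - {strand: bottom, position: 50, kind: methyl_C, initiation_delay_s: 150}
      - {strand: bottom, position: 70, kind: methyl_C, initiation_delay_s: 150}
  # --- nick / gap / nickase substrates (ends doubly blocked) ------------
  - {name: S_b3b3_nick, duplex_length: 80, blocked_ends: [top3, bot3],
     nicks: [[top, 60]]}
  - {name: S_b3b3_gap, duplex_length: 80, blocked_ends: [top3, bot3],
     gaps: [[top, 58, 3]]}
  - name: S_b3b3_motifs   # five CCA sites on one strand, two CCT on the other
    duplex_length: 80
    blocked_ends: [top3, bot3]
    motif_sites:
      - [top, 10, CCA]
      - [top, 25, CCA]
      - [top, 40, CCA]
      - [top, 55, CCA]
      - [top, 70, CCA]
      - [bottom, 30, CCT]
      - [bottom, 60, CCT]
  - {name: S_b5b5_nick, duplex_length: 80, blocked_ends: [top5, bot5],
     nicks: [[top, 20]]}
  - {name: S_b5b5_gap, duplex_length: 80, blocked_ends: [top5, bot5],
     gaps: [[top, 19, 3]]}
  # --- single-stranded DNA ---------------------------------------------
  - {name: ss20, nucleic_kind: ssDNA, ss_length: 20}
  - {name: ss40, nucleic_kind: ssDNA, ss_length: 40}
  - {name: ss60, nucleic_kind: ssDNA, ss_length: 60}
  - {name: ss80, nucleic_kind: ssDNA, ss_length: 80}
  # --- primer-template (polymerase mode): primer annealed on 80-mer -----
  - {name: pt_primer20, duplex_length: 80, is_primer_template: true, primer_length: 20}
  - {name: pt_primer40, duplex_length: 80, is_primer_template: true, primer_length: 40}
  - {name: pt_primer60, duplex_length: 80, is_primer_template: true, primer_length: 60}
  # --- RNA substrates (RNA dye mode) ------------------------------------
  - {name: rna20, nucleic_kind: ssRNA, ss_length: 20}
  - {name: rna40, nucleic_kind: ssRNA, ss_length: 40}
  - {name: hybrid20, nucleic_kind: RNA_DNA_hybrid, duplex_length: 20}
  - {name: hybrid40, nucleic_kind: RNA_DNA_hybrid, duplex_length: 40}
  - {name: dsrna20, nucleic_kind: dsRNA, duplex_length: 20}
  - {name: dsrna40, nucleic_kind: dsRNA, duplex_length: 40}

enzymes:
  - name: DNase I
    directionality: nonspecific
    rate: 0.001            # bp nM^-1 s^-1 bulk digestion rate, 80-bp duplex
    rate_basis: per_nt_hazard
    ref_length: 80
    initiates_at: [blunt_end, overhang_end]
  - name: ExoIII
    directionality: 3to5
    rate: 0.005            # five-fold the DNase rate; one-blocked 80-bp duplex
    rate_basis: bulk_one_blocked
    max_permissive_overhang: 3   # 2-nt permissive, 4-nt fully inhibitory
    overhang_rate_attenuation: {2: 0.9}
    initiates_at: [blunt_end, overhang_end, nick, gap]
    site_multipliers: {nick: 1.0, gap: 1.15}  # marginal preference for gaps
  - name: T7 Exo
    directionality: 5to3
    rate: 0.004            # bulk rate on the one-blocked blunt substrate
    rate_basis: bulk_one_blocked
    max_permissive_overhang: null   # limited, never fully inhibited
    overhang_rate_attenuation: {2: 1.0, 10: 0.85, 20: 0.5}
    initiates_at: [blunt_end, overhang_end, nick, gap]
    site_multipliers: {nick: 0.4, gap: 1.0}   # ~2.5-fold preference for gaps
  - name: Trex2
    directionality: ss_only
    rate: 2.5e-4           # nt nM^-1 s^-1, mid-range of the reported band
    rate_basis: per_front
    initiates_at: [ss_terminus]
  - name: Klenow
    directionality: polymerase
    rate: 0.05             # bp nM^-1 s^-1 on the 60-nt template overhang
    rate_basis: per_front
    overhang_rate_attenuation: {20: 0.3333333333, 40: 0.3333333333, 60: 1.0}
    initiates_at: []
  - name: RNase A
    directionality: rna_ss
    rate: 180.0            # nt nM^-1 s^-1 on the 20-nt ssRNA substrate
    rate_basis: per_front
    initiates_at: [ss_terminus]
  - name: RNase H
    directionality: rna_hybrid
    rate: 2.0e-5           # nt nM^-1 s^-1 on the 20-bp hybrid
    rate_basis: per_nt_hazard
    ref_length: 20
    initiates_at: [rna_of_hybrid]
  - name: Nt.CviPII
    directionality: nickase
    rate: 1.0
    rate_basis: nicking
    motif: {CCA: 5.0e-4, CCG: 5.0e-4, CCT: 1.0e-4}   # per-site s^-1 nM^-1
    initiates_at: []
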