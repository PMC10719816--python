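# Demonstration 3-tier emotion lexicon (Parrott-style hierarchy).
# Schema: one entry per class with label, tier (primary|secondary|tertiary),
# parent (absent for the six fixed primaries) and an optional synonym list.
# The declared counts below cover non-primary classes and all synonyms and
# must agree with the recomputed manifest.
name: demo-parrott
n_subclasses: 27
n_synonyms: 86
classes:
  - {label: joy, tier: primary}
  - {label: love, tier: primary}
  - {label: surprise, tier: primary}
  - {label: sadness, tier: primary}
  - {label: fear, tier: primary}
  - {label: anger, tier: primary}

  # ---- joy -------------------------------------------------------------
  - {label: cheerfulness, tier: secondary, parent: joy}
  - label: delight
    tier: tertiary
    parent: cheerfulness
    synonyms: [delighted, thrilled, glee, bliss, happy, happiness, joyful,
               cheerful, ecstatic, elated, overjoyed]
  - label: contentment
    tier: tertiary
    parent: cheerfulness
    synonyms: [contented, gratified, fulfilled]
  - {label: pride, tier: secondary, parent: joy}
  - label: triumph
    tier: tertiary
    parent: pride
    synonyms: [triumphant, proud]

  # ---- love ------------------------------------------------------------
  - label: affection
    tier: secondary
    parent: love
    synonyms: [fond, fondness, tender, tenderness]
  - label: adoration
    tier: tertiary
    parent: affection
    synonyms: [adore, adored, adoring, cherish, cherished]
  - {label: desire, tier: secondary, parent: love}
  - label: passion
    tier: tertiary
    parent: desire
    synonyms: [passionate, romance, romantic, yearning]

  # ---- surprise ----------------------------------------------------------
  - {label: amazement, tier: secondary, parent: surprise}
  - label: astonishment
    tier: tertiary
    parent: amazement
    synonyms: [astonished, amazed, astounded, stunned, startled, speechless, wow]

  # ---- sadness -----------------------------------------------------------
  - label: melancholy
    tier: secondary
    parent: sadness
    synonyms: [sad, unhappy, gloomy, miserable, hopeless]
  - {label: suffering, tier: secondary, parent: sadness}
  - label: agony
    tier: tertiary
    parent: suffering
    synonyms: [anguish, torment, hurting]
  - {label: disappointment, tier: secondary, parent: sadness}
  - label: dismay
    tier: tertiary
    parent: disappointment
    synonyms: [disappointed, disappointing, let down, letdown, displeased]
  - label: grief
    tier: secondary
    parent: sadness
    synonyms: [sorrow, mourning]
  - label: heartbroken
    tier: tertiary
    parent: grief
    synonyms: [heartbreak, devastated]

  # ---- fear --------------------------------------------------------------
  - {label: horror, tier: secondary, parent: fear}
  - label: terror
    tier: tertiary
    parent: horror
    synonyms: [terrified, terrifying, panic, fright, frightened, horrified]
  - {label: nervousness, tier: secondary, parent: fear}
  - label: anxiety
    tier: tertiary
    parent: nervousness
    synonyms: [anxious, worry, worried, uneasy, dread, apprehensive, tense,
               nervous, afraid]

  # ---- anger -------------------------------------------------------------
  - {label: rage, tier: secondary, parent: anger}
  - label: fury
    tier: tertiary
    parent: rage
    synonyms: [furious, outraged, outrage, wrath, livid]
  - {label: irritation, tier: secondary, parent: anger}
  - label: annoyance
    tier: tertiary
    parent: irritation
    synonyms: [annoyed, annoying, irritated, irritating, aggravated,
               frustrated, frustrating, grouchy]
  - label: disgust
    tier: secondary
    parent: anger
    synonyms: [disgusted, disgusting, revolted, repulsed, contempt]
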