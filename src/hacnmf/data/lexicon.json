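{
  "comment": "Synthetic lexicon for the formant synthesizer. Phone symbols are internal labels, not IPA. Formants in Hz (voiced phones), noise bands in Hz (unvoiced), durations in seconds. Carrier sentences are invented: the corpus design only fixes that keywords appear sentence-initially or -finally inside short carrier phrases. Carrier words and the foil 'edible' pronunciation are likewise invented for this synthetic lexicon.",
  "phones": {
    "a": {"kind": "vowel", "voiced": true, "formants": [700, 1200, 2600], "duration": 0.115, "amplitude": 1.0},
    "e": {"kind": "vowel", "voiced": true, "formants": [480, 1900, 2550], "duration": 0.110, "amplitude": 1.0},
    "i": {"kind": "vowel", "voiced": true, "formants": [300, 2300, 3000], "duration": 0.105, "amplitude": 0.9},
    "o": {"kind": "vowel", "voiced": true, "formants": [450, 850, 2600], "duration": 0.115, "amplitude": 1.0},
    "u": {"kind": "vowel", "voiced": true, "formants": [320, 750, 2450], "duration": 0.105, "amplitude": 0.9},
    "m": {"kind": "nasal", "voiced": true, "formants": [250, 1100, 2200], "duration": 0.080, "amplitude": 0.55},
    "n": {"kind": "nasal", "voiced": true, "formants": [300, 1650, 2600], "duration": 0.080, "amplitude": 0.55},
    "l": {"kind": "liquid", "voiced": true, "formants": [380, 1500, 2500], "duration": 0.075, "amplitude": 0.7},
    "r": {"kind": "liquid", "voiced": true, "formants": [420, 1250, 1650], "duration": 0.075, "amplitude": 0.7},
    "w": {"kind": "liquid", "voiced": true, "formants": [300, 650, 2300], "duration": 0.070, "amplitude": 0.65},
    "b": {"kind": "vstop", "voiced": true, "formants": [350, 900, 2300], "duration": 0.060, "amplitude": 0.6, "closure": 0.030},
    "d": {"kind": "vstop", "voiced": true, "formants": [350, 1700, 2600], "duration": 0.060, "amplitude": 0.6, "closure": 0.030},
    "g": {"kind": "vstop", "voiced": true, "formants": [350, 2000, 2500], "duration": 0.060, "amplitude": 0.6, "closure": 0.030},
    "p": {"kind": "ustop", "voiced": false, "band": [500, 1500], "duration": 0.055, "amplitude": 0.45, "closure": 0.040},
    "t": {"kind": "ustop", "voiced": false, "band": [2500, 4500], "duration": 0.055, "amplitude": 0.45, "closure": 0.040},
    "k": {"kind": "ustop", "voiced": false, "band": [1300, 2600], "duration": 0.055, "amplitude": 0.45, "closure": 0.040},
    "s": {"kind": "fricative", "voiced": false, "band": [3200, 6800], "duration": 0.095, "amplitude": 0.4},
    "f": {"kind": "fricative", "voiced": false, "band": [1200, 4500], "duration": 0.090, "amplitude": 0.35}
  },
  "words": {
    "animal": {"phones": ["a", "n", "i", "m", "a", "l"], "syllables": 3, "role": "keyword"},
    "apple": {"phones": ["a", "p", "a", "l"], "syllables": 2, "role": "keyword"},
    "banana": {"phones": ["b", "a", "n", "a", "n", "a"], "syllables": 3, "role": "keyword"},
    "baby": {"phones": ["b", "e", "b", "i"], "syllables": 2, "role": "keyword"},
    "bird": {"phones": ["b", "e", "r", "d"], "syllables": 1, "role": "keyword"},
    "bottle": {"phones": ["b", "o", "t", "a", "l"], "syllables": 2, "role": "keyword"},
    "car": {"phones": ["k", "a", "r"], "syllables": 1, "role": "keyword"},
    "cat": {"phones": ["k", "a", "t"], "syllables": 1, "role": "keyword"},
    "cookie": {"phones": ["k", "u", "k", "i"], "syllables": 2, "role": "keyword"},
    "daddy": {"phones": ["d", "a", "d", "i"], "syllables": 2, "role": "keyword"},
    "dog": {"phones": ["d", "o", "g"], "syllables": 1, "role": "keyword"},
    "mummy": {"phones": ["m", "a", "m", "i"], "syllables": 2, "role": "keyword"},
    "telephone": {"phones": ["t", "e", "l", "e", "f", "o", "n"], "syllables": 3, "role": "keyword"},
    "toy": {"phones": ["t", "o", "i"], "syllables": 1, "role": "keyword"},
    "truck": {"phones": ["t", "r", "a", "k"], "syllables": 1, "role": "keyword"},
    "ball": {"phones": ["b", "o", "l"], "syllables": 1, "role": "foil"},
    "cow": {"phones": ["k", "a", "w"], "syllables": 1, "role": "foil"},
    "red": {"phones": ["r", "e", "d"], "syllables": 1, "role": "foil"},
    "woman": {"phones": ["w", "u", "m", "a", "n"], "syllables": 2, "role": "foil"},
    "robin": {"phones": ["r", "o", "b", "i", "n"], "syllables": 2, "role": "foil"},
    "airplane": {"phones": ["e", "r", "p", "l", "e", "n"], "syllables": 2, "role": "foil"},
    "edible": {"phones": ["e", "d", "i", "b", "a", "l"], "syllables": 3, "role": "foil"},
    "this": {"phones": ["d", "i", "s"], "syllables": 1, "role": "carrier"},
    "is": {"phones": ["i", "s"], "syllables": 1, "role": "carrier"},
    "a": {"phones": ["a"], "syllables": 1, "role": "carrier"},
    "nice": {"phones": ["n", "a", "i", "s"], "syllables": 1, "role": "carrier"},
    "where": {"phones": ["w", "e", "r"], "syllables": 1, "role": "carrier"},
    "the": {"phones": ["d", "a"], "syllables": 1, "role": "carrier"},
    "happy": {"phones": ["a", "p", "i"], "syllables": 2, "role": "carrier"},
    "look": {"phones": ["l", "u", "k"], "syllables": 1, "role": "carrier"},
    "at": {"phones": ["a", "t"], "syllables": 1, "role": "carrier"},
    "i": {"phones": ["i"], "syllables": 1, "role": "carrier"},
    "see": {"phones": ["s", "i"], "syllables": 1, "role": "carrier"},
    "so": {"phones": ["s", "o"], "syllables": 1, "role": "carrier"},
    "over": {"phones": ["o", "w", "e", "r"], "syllables": 2, "role": "carrier"},
    "there": {"phones": ["d", "e", "r"], "syllables": 1, "role": "carrier"},
    "comes": {"phones": ["k", "a", "m", "s"], "syllables": 1, "role": "carrier"},
    "along": {"phones": ["a", "l", "o", "n"], "syllables": 2, "role": "carrier"},
    "for": {"phones": ["f", "o", "r"], "syllables": 1, "role": "carrier"},
    "you": {"phones": ["u"], "syllables": 1, "role": "carrier"}
  },
  "carriers": {
    "c1": {"words": ["this", "is", "a", "nice"], "position": "final"},
    "c2": {"words": ["where", "is", "the", "happy"], "position": "final"},
    "c3": {"words": ["look", "at", "the"], "position": "final"},
    "c4": {"words": ["i", "see", "a"], "position": "final"},
    "c5": {"words": ["is", "so", "nice"], "position": "initial"},
    "c6": {"words": ["is", "over", "there"], "position": "initial"},
    "c7": {"words": ["comes", "along"], "position": "initial"},
    "c8": {"words": ["is", "for", "you"], "position": "initial"}
  }
}
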