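# Default keyword lexicons for the 8 atopic-dermatitis indicator categories.
# One list per category id. Entries are case-insensitive whole phrases unless
# prefixed with "re:", in which case they are raw regular expressions.
# Categories:
#   1 direct mention of AD            5 dry or itchy skin
#   2 hay fever allergies             6 non-asthma medications (AD treatment)
#   3 atopic allergies                7 asthma
#   4 eczema or rashes                8 asthma medications
1:
  - atopic dermatitis
  - atopic eczema
  - neurodermatitis
  - besnier prurigo
2:
  - hay fever
  - hayfever
  - allergic rhinitis
  - seasonal allergies
  - grass pollen allergy
3:
  - atopy
  - atopic allergy
  - atopic allergies
  - food allergy
  - peanut allergy
  - egg allergy
  - allergic conjunctivitis
4:
  - eczema
  - eczematous
  - rash
  - rashes
  - dermatitis
  - flexural involvement
5:
  - itchy
  - itching
  - itchy skin
  - pruritus
  - pruritic
  - dry skin
  - xerosis
6:
  - triamcinolone
  - hydrocortisone
  - tacrolimus
  - pimecrolimus
  - crisaborole
  - dupilumab
  - emollients
  - moisturizing cream
7:
  - asthma
  - asthmatic
  - wheezing
  - reactive airway disease
8:
  - benralizumab
  - mepolizumab
  - omalizumab
  - atrovent hfa
  - flovent hfa
  - xopenex hfa
  - albuterol
  - montelukast
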