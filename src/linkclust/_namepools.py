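"""Bundled name pools for the synthetic record generator.

Small static lists of common English given names (with gender tag),
surnames, a nickname table, and homophone substitution rules used for
phonetically plausible misspellings.  They keep the repository
self-contained; they make no claim of demographic representativeness
beyond exercising the string distances.
"""

FIRST_NAMES: list[tuple[str, str]] = [
    # (name, gender)
    ("james", "m"), ("john", "m"), ("robert", "m"), ("michael", "m"),
    ("william", "m"), ("david", "m"), ("richard", "m"), ("joseph", "m"),
    ("thomas", "m"), ("charles", "m"), ("christopher", "m"), ("daniel", "m"),
    ("matthew", "m"), ("anthony", "m"), ("donald", "m"), ("mark", "m"),
    ("paul", "m"), ("steven", "m"), ("andrew", "m"), ("kenneth", "m"),
    ("joshua", "m"), ("kevin", "m"), ("brian", "m"), ("george", "m"),
    ("edward", "m"), ("ronald", "m"), ("timothy", "m"), ("jason", "m"),
    ("jeffrey", "m"), ("ryan", "m"), ("jacob", "m"), ("gary", "m"),
    ("nicholas", "m"), ("eric", "m"), ("jonathan", "m"), ("stephen", "m"),
    ("larry", "m"), ("justin", "m"), ("scott", "m"), ("brandon", "m"),
    ("benjamin", "m"), ("samuel", "m"), ("gregory", "m"), ("frank", "m"),
    ("alexander", "m"), ("raymond", "m"), ("patrick", "m"), ("jack", "m"),
    ("dennis", "m"), ("jerry", "m"), ("tyler", "m"), ("aaron", "m"),
    ("jose", "m"), ("adam", "m"), ("henry", "m"), ("nathan", "m"),
    ("douglas", "m"), ("zachary", "m"), ("peter", "m"), ("kyle", "m"),
    ("walter", "m"), ("ethan", "m"), ("jeremy", "m"), ("harold", "m"),
    ("keith", "m"), ("christian", "m"), ("roger", "m"), ("noah", "m"),
    ("gerald", "m"), ("carl", "m"), ("terry", "m"), ("sean", "m"),
    ("austin", "m"), ("arthur", "m"), ("lawrence", "m"), ("jesse", "m"),
    ("dylan", "m"), ("bryan", "m"), ("joe", "m"), ("jordan", "m"),
    ("billy", "m"), ("bruce", "m"), ("albert", "m"), ("willie", "m"),
    ("gabriel", "m"), ("logan", "m"), ("alan", "m"), ("juan", "m"),
    ("wayne", "m"), ("roy", "m"), ("ralph", "m"), ("randy", "m"),
    ("eugene", "m"), ("vincent", "m"), ("russell", "m"), ("elijah", "m"),
    ("louis", "m"), ("bobby", "m"), ("philip", "m"), ("johnny", "m"),
    ("mary", "f"), ("patricia", "f"), ("jennifer", "f"), ("linda", "f"),
    ("elizabeth", "f"), ("barbara", "f"), ("susan", "f"), ("jessica", "f"),
    ("sarah", "f"), ("karen", "f"), ("nancy", "f"), ("lisa", "f"),
    ("betty", "f"), ("margaret", "f"), ("sandra", "f"), ("ashley", "f"),
    ("kimberly", "f"), ("emily", "f"), ("donna", "f"), ("michelle", "f"),
    ("dorothy", "f"), ("carol", "f"), ("amanda", "f"), ("melissa", "f"),
    ("deborah", "f"), ("stephanie", "f"), ("rebecca", "f"), ("sharon", "f"),
    ("laura", "f"), ("cynthia", "f"), ("kathleen", "f"), ("amy", "f"),
    ("shirley", "f"), ("angela", "f"), ("helen", "f"), ("anna", "f"),
    ("brenda", "f"), ("pamela", "f"), ("nicole", "f"), ("emma", "f"),
    ("samantha", "f"), ("katherine", "f"), ("christine", "f"), ("debra", "f"),
    ("rachel", "f"), ("catherine", "f"), ("carolyn", "f"), ("janet", "f"),
    ("ruth", "f"), ("maria", "f"), ("heather", "f"), ("diane", "f"),
    ("virginia", "f"), ("julie", "f"), ("joyce", "f"), ("victoria", "f"),
    ("olivia", "f"), ("kelly", "f"), ("christina", "f"), ("lauren", "f"),
    ("joan", "f"), ("evelyn", "f"), ("judith", "f"), ("megan", "f"),
    ("cheryl", "f"), ("andrea", "f"), ("hannah", "f"), ("martha", "f"),
    ("jacqueline", "f"), ("frances", "f"), ("gloria", "f"), ("ann", "f"),
    ("teresa", "f"), ("kathryn", "f"), ("sara", "f"), ("janice", "f"),
    ("jean", "f"), ("alice", "f"), ("madison", "f"), ("doris", "f"),
    ("abigail", "f"), ("julia", "f"), ("judy", "f"), ("grace", "f"),
    ("denise", "f"), ("amber", "f"), ("marilyn", "f"), ("beverly", "f"),
    ("danielle", "f"), ("theresa", "f"), ("sophia", "f"), ("marie", "f"),
    ("diana", "f"), ("brittany", "f"), ("natalie", "f"), ("isabella", "f"),
    ("charlotte", "f"), ("rose", "f"), ("alexis", "f"), ("kayla", "f"),
]

SURNAMES: list[str] = [
    "smith", "johnson", "williams", "brown", "jones", "garcia", "miller",
    "davis", "rodriguez", "martinez", "hernandez", "lopez", "gonzalez",
    "wilson", "anderson", "thomas", "taylor", "moore", "jackson", "martin",
    "lee", "perez", "thompson", "white", "harris", "sanchez", "clark",
    "ramirez", "lewis", "robinson", "walker", "young", "allen", "king",
    "wright", "scott", "torres", "nguyen", "hill", "flores", "green",
    "adams", "nelson", "baker", "hall", "rivera", "campbell", "mitchell",
    "carter", "roberts", "gomez", "phillips", "evans", "turner", "diaz",
    "parker", "cruz", "edwards", "collins", "reyes", "stewart", "morris",
    "morales", "murphy", "cook", "rogers", "gutierrez", "ortiz", "morgan",
    "cooper", "peterson", "bailey", "reed", "kelly", "howard", "ramos",
    "kim", "cox", "ward", "richardson", "watson", "brooks", "chavez",
    "wood", "james", "bennett", "gray", "mendoza", "ruiz", "hughes",
    "price", "alvarez", "castillo", "sanders", "patel", "myers", "long",
    "ross", "foster", "jimenez", "powell", "jenkins", "perry", "russell",
    "sullivan", "bell", "coleman", "butler", "henderson", "barnes",
    "gonzales", "fisher", "vasquez", "simmons", "romero", "jordan",
    "patterson", "alexander", "hamilton", "graham", "reynolds", "griffin",
    "wallace", "moreno", "west", "cole", "hayes", "bryant", "herrera",
    "gibson", "ellis", "tran", "medina", "aguilar", "stevens", "murray",
    "ford", "castro", "marshall", "owens", "harrison", "fernandez",
    "mcdonald", "woods", "washington", "kennedy", "wells", "vargas",
    "henry", "chen", "freeman", "webb", "tucker", "guzman", "burns",
    "crawford", "olson", "simpson", "porter", "hunter", "gordon", "mendez",
    "silva", "shaw", "snyder", "mason", "dixon", "munoz", "hunt", "hicks",
    "holmes", "palmer", "wagner", "black", "robertson", "boyd", "rose",
    "stone", "salazar", "fox", "warren", "mills", "meyer", "rice",
    "schmidt", "garza", "daniels", "ferguson", "nichols", "stephens",
    "soto", "weaver", "ryan", "gardner", "payne", "grant", "dunn",
    "kelley", "spencer", "hawkins", "arnold", "pierce", "vazquez",
    "hansen", "peters", "santos", "hart", "bradley", "knight", "elliott",
    "cunningham", "duncan", "armstrong", "hudson", "carroll", "lane",
    "riley", "andrews", "alvarado", "ray", "delgado", "berry", "perkins",
    "hoffman", "johnston", "matthews", "pena", "richards", "contreras",
    "willis", "carpenter", "lawrence", "sandoval", "guerrero", "george",
    "chapman", "rios", "estrada", "ortega", "watkins", "greene", "nunez",
    "wheeler", "valdez", "harper", "burke", "larson", "santiago",
    "maldonado", "morrison", "franklin", "carlson", "austin", "dominguez",
    "carr", "lawson", "jacobs", "obrien", "lynch", "singh", "vega",
    "bishop", "montgomery", "oliver", "jensen", "harvey", "williamson",
    "gilbert", "dean", "sims", "espinoza", "howell", "li", "wong",
    "reid", "hanson", "le", "mccoy", "garrett", "burton", "fuller",
    "wang", "weber", "welch", "rojas", "lucas", "marquez", "fields",
    "park", "yang", "little", "banks", "padilla", "day", "walsh",
    "bowman", "schultz", "luna", "fowler", "mejia", "davidson", "acosta",
    "brewer", "may", "holland", "juarez", "newman", "pearson", "curtis",
    "cortez", "douglas", "schneider", "joseph", "barrett", "navarro",
    "figueroa", "keller", "avila", "wade", "molina", "stanley", "hopkins",
    "campos", "barnett", "bates", "chambers", "caldwell", "beck", "lambert",
    "miranda", "byrd", "craig", "ayala", "lowe", "frazier", "powers",
    "neal", "leonard", "gregory", "carrillo", "sutton", "fleming", "rhodes",
    "shelton", "schwartz", "norris", "jennings", "watts", "duran",
    "walters", "cohen", "mcdaniel", "moran", "parks", "steele", "vaughn",
    "becker", "holt", "deleon", "barker", "terry", "hale", "leon", "hail",
]

# Symmetric nickname pairs (full name, short form); closure applied on load.
NICKNAME_PAIRS: list[tuple[str, str]] = [
    ("james", "jim"), ("james", "jimmy"), ("john", "jack"), ("john", "johnny"),
    ("robert", "bob"), ("robert", "rob"), ("robert", "bobby"),
    ("michael", "mike"), ("michael", "mickey"),
    ("william", "bill"), ("william", "will"), ("william", "billy"),
    ("david", "dave"), ("richard", "rick"), ("richard", "dick"),
    ("joseph", "joe"), ("joseph", "joey"), ("thomas", "tom"), ("thomas", "tommy"),
    ("charles", "charlie"), ("charles", "chuck"),
    ("christopher", "chris"), ("daniel", "dan"), ("daniel", "danny"),
    ("matthew", "matt"), ("anthony", "tony"), ("donald", "don"),
    ("steven", "steve"), ("andrew", "andy"), ("andrew", "drew"),
    ("kenneth", "ken"), ("kenneth", "kenny"), ("joshua", "josh"),
    ("edward", "ed"), ("edward", "eddie"), ("edward", "ted"),
    ("ronald", "ron"), ("timothy", "tim"), ("jeffrey", "jeff"),
    ("jacob", "jake"), ("nicholas", "nick"), ("jonathan", "jon"),
    ("stephen", "steve"), ("justin", "jus"), ("benjamin", "ben"),
    ("samuel", "sam"), ("gregory", "greg"), ("alexander", "alex"),
    ("raymond", "ray"), ("patrick", "pat"), ("dennis", "denny"),
    ("jeremy", "jem"), ("zachary", "zach"), ("peter", "pete"),
    ("walter", "walt"), ("harold", "hal"), ("gerald", "gerry"),
    ("lawrence", "larry"), ("jesse", "jess"), ("albert", "al"),
    ("gabriel", "gabe"), ("vincent", "vince"), ("vincent", "vinny"),
    ("russell", "russ"), ("louis", "lou"), ("philip", "phil"),
    ("eugene", "gene"), ("douglas", "doug"), ("nathan", "nate"),
    ("frank", "frankie"), ("henry", "hank"),
    ("patricia", "pat"), ("patricia", "patty"), ("patricia", "trish"),
    ("jennifer", "jen"), ("jennifer", "jenny"),
    ("elizabeth", "liz"), ("elizabeth", "beth"), ("elizabeth", "betsy"),
    ("elizabeth", "lizzie"), ("barbara", "barb"), ("barbara", "barbie"),
    ("susan", "sue"), ("susan", "susie"), ("jessica", "jess"),
    ("jessica", "jessie"), ("karen", "kari"), ("nancy", "nan"),
    ("margaret", "meg"), ("margaret", "peggy"), ("margaret", "maggie"),
    ("sandra", "sandy"), ("kimberly", "kim"), ("emily", "em"),
    ("michelle", "shelly"), ("dorothy", "dot"), ("dorothy", "dottie"),
    ("amanda", "mandy"), ("melissa", "mel"), ("melissa", "missy"),
    ("deborah", "deb"), ("deborah", "debbie"), ("stephanie", "steph"),
    ("rebecca", "becky"), ("cynthia", "cindy"), ("kathleen", "kathy"),
    ("kathleen", "kate"), ("angela", "angie"), ("pamela", "pam"),
    ("nicole", "nikki"), ("samantha", "sam"), ("katherine", "kathy"),
    ("katherine", "kate"), ("katherine", "katie"), ("christine", "chris"),
    ("christine", "chrissy"), ("debra", "deb"), ("rachel", "rae"),
    ("catherine", "cathy"), ("catherine", "cat"), ("janet", "jan"),
    ("victoria", "vicky"), ("victoria", "tori"), ("olivia", "liv"),
    ("christina", "tina"), ("christina", "chris"), ("judith", "judy"),
    ("megan", "meg"), ("andrea", "andi"), ("jacqueline", "jackie"),
    ("frances", "fran"), ("frances", "frannie"), ("teresa", "terry"),
    ("kathryn", "kate"), ("abigail", "abby"), ("julia", "jules"),
    ("beverly", "bev"), ("danielle", "dani"), ("theresa", "terry"),
    ("diana", "di"), ("brittany", "britt"), ("natalie", "nat"),
    ("isabella", "bella"), ("isabella", "izzy"), ("charlotte", "lottie"),
    ("alexis", "lexi"), ("virginia", "ginny"), ("florence", "flo"),
]

# Homophone substitution rules for phonetically plausible misspellings.
# Applied anywhere in a name; both directions are listed where sensible.
PHONETIC_RULES: list[tuple[str, str]] = [
    ("ph", "f"), ("f", "ph"),
    ("ck", "k"), ("k", "ck"),
    ("i", "y"), ("y", "i"),
    ("s", "z"), ("z", "s"),
    ("c", "k"), ("ee", "ea"),
    ("ou", "u"), ("gh", "g"),
    ("mb", "m"), ("kn", "n"),
    ("wr", "r"), ("x", "ks"),
]
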