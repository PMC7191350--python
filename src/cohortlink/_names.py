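"""Bundled static name lists for the synthetic identity generator.

A pluggable provider interface: any object with ``first_names`` and
``last_names`` sequences works. The bundled lists deliberately include
short names, apostrophes, hyphens, and diacritics so that name
normalization and the partial-name match keys are exercised.
"""

FIRST_NAMES: tuple[str, ...] = (
    "James", "Mary", "Robert", "Patricia", "John", "Jennifer", "Michael",
    "Linda", "David", "Elizabeth", "William", "Barbara", "Richard", "Susan",
    "Joseph", "Jessica", "Thomas", "Sarah", "Charles", "Karen", "Christopher",
    "Lisa", "Daniel", "Nancy", "Matthew", "Betty", "Anthony", "Margaret",
    "Mark", "Sandra", "Donald", "Ashley", "Steven", "Kimberly", "Andrew",
    "Emily", "Paul", "Donna", "Joshua", "Michelle", "Kenneth", "Carol",
    "Kevin", "Amanda", "Brian", "Dorothy", "George", "Melissa", "Timothy",
    "Deborah", "Ronald", "Stephanie", "Edward", "Rebecca", "Jason", "Sharon",
    "Jeffrey", "Laura", "Ryan", "Cynthia", "Jacob", "Kathleen", "Gary",
    "Amy", "Nicholas", "Angela", "Eric", "Shirley", "Jonathan", "Anna",
    "Stephen", "Brenda", "Larry", "Pamela", "Justin", "Emma", "Scott",
    "Nicole", "Brandon", "Helen", "Benjamin", "Samantha", "Samuel",
    "Katherine", "Gregory", "Christine", "Alexander", "Debra", "Patrick",
    "Rachel", "Frank", "Carolyn", "Raymond", "Janet", "Jack", "Catherine",
    "Dennis", "Maria", "Jerry", "Heather", "Tyler", "Diane", "Aaron",
    "Ruth", "Jose", "Julie", "Adam", "Olivia", "Nathan", "Joyce", "Henry",
    "Virginia", "Douglas", "Victoria", "Zachary", "Kelly", "Peter",
    "Lauren", "Kyle", "Christina", "Ethan", "Joan", "Walter", "Evelyn",
    "Noah", "Judith", "Jeremy", "Megan", "Christian", "Andrea", "Keith",
    "Cheryl", "Roger", "Hannah", "Terry", "Jacqueline", "Gerald", "Martha",
    "Harold", "Gloria", "Sean", "Teresa", "Austin", "Ann", "Carl", "Sara",
    "Arthur", "Madison", "Lawrence", "Frances", "Dylan", "Kathryn",
    "Jesse", "Janice", "Jordan", "Jean", "Bryan", "Abigail", "Billy",
    "Alice", "Joe", "Julia", "Bruce", "Judy", "Gabriel", "Sofía", "Logan",
    "Grace", "Albert", "Denise", "Willie", "Amber", "Alan", "Doris",
    "Juan", "Marilyn", "Wayne", "Danielle", "Elijah", "Beverly", "Randy",
    "Isabella", "Roy", "Theresa", "Vincent", "Diana", "Ralph", "Natalie",
    "Eugene", "Brittany", "Russell", "Charlotte", "Bobby", "Marie",
    "Mason", "Kayla", "Philip", "Alexis", "Louis", "Lori", "André",
    "Renée", "Al", "Bo", "Ty", "Li", "José", "Inés", "Zoë", "D'Angelo",
    "Mary-Kate", "Jean-Paul",
)

LAST_NAMES: tuple[str, ...] = (
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green",
    "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
    "Carter", "Roberts", "Gomez", "Phillips", "Evans", "Turner", "Diaz",
    "Parker", "Cruz", "Edwards", "Collins", "Reyes", "Stewart", "Morris",
    "Morales", "Murphy", "Cook", "Rogers", "Gutierrez", "Ortiz", "Morgan",
    "Cooper", "Peterson", "Bailey", "Reed", "Kelly", "Howard", "Ramos",
    "Kim", "Cox", "Ward", "Richardson", "Watson", "Brooks", "Chavez",
    "Wood", "James", "Bennett", "Gray", "Mendoza", "Ruiz", "Hughes",
    "Price", "Alvarez", "Castillo", "Sanders", "Patel", "Myers", "Long",
    "Ross", "Foster", "Jimenez", "Powell", "Jenkins", "Perry", "Russell",
    "Sullivan", "Bell", "Coleman", "Butler", "Henderson", "Barnes",
    "Gonzales", "Fisher", "Vasquez", "Simmons", "Romero", "Jordan",
    "Patterson", "Alexander", "Hamilton", "Graham", "Reynolds", "Griffin",
    "Wallace", "Moreno", "West", "Cole", "Hayes", "Bryant", "Herrera",
    "Gibson", "Ellis", "Tran", "Medina", "Aguilar", "Stevens", "Murray",
    "Ford", "Castro", "Marshall", "Owens", "Harrison", "Fernandez",
    "McDonald", "Woods", "Washington", "Kennedy", "Wells", "Vargas",
    "Henry", "Chen", "Freeman", "Webb", "Tucker", "Guzman", "Burns",
    "Crawford", "Olson", "Simpson", "Porter", "Hunter", "Gordon", "Mendez",
    "Silva", "Shaw", "Snyder", "Mason", "Dixon", "Muñoz", "Hunt", "Hicks",
    "Holmes", "Palmer", "O'Brien", "O'Neil", "D'Amico", "St. Clair",
    "van Dyke", "De la Cruz", "Núñez", "Löwe", "Ng", "Wu", "Xu", "Oh",
    "Smith-Jones", "García-López",
)
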